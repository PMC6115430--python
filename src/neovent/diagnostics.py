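"""Post-processing diagnostics: flow regimes, leak fraction, run summary.

The 3D gas-exchange mechanisms (turbulent vortices in the large airways,
laminar flow beyond roughly generation six, pendelluft, direct ventilation
of proximal regions) leave reduced-order signatures that are computed here.
Turbulence cannot be resolved in a 0D/1D model; instead each segment is
classified by its peak-cycle Reynolds number against declared, configurable
thresholds, together with the Womersley number of the oscillatory regime.
These thresholds are surrogates and are reported alongside the labels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .airway_tree import AirwayTree, dead_space
from .flow_solver import SimulationResult, detect_steady_state
from .mechanics import AirProperties
from .ventilator import HFOVSettings

__all__ = [
    "RegimeReport",
    "RunSummary",
    "reynolds_number",
    "womersley_number",
    "classify_regimes",
    "leak_fraction",
    "summarise_run",
]

#: default Reynolds thresholds (transitional lower bound, turbulent-prone bound)
DEFAULT_RE_THRESHOLDS = (500.0, 2000.0)


def reynolds_number(
    diameter_mm: float, peak_flow_ml_s: float, air: AirProperties = AirProperties()
) -> float:
    """Peak Reynolds number Re = 4 |Q| / (pi d nu) = u d / nu with u = Q/A."""
    q_mm3 = abs(peak_flow_ml_s) * 1e3
    return 4.0 * q_mm3 / (math.pi * diameter_mm * air.kinematic_viscosity)


def womersley_number(
    diameter_mm: float, frequency_hz: float, air: AirProperties = AirProperties()
) -> float:
    """Womersley number alpha = (d/2) sqrt(2 pi f / nu)."""
    return (diameter_mm / 2.0) * math.sqrt(
        2.0 * math.pi * frequency_hz / air.kinematic_viscosity
    )


@dataclass
class RegimeReport:
    """Per-segment oscillatory flow-regime classification."""

    table: pd.DataFrame  # segment_id, generation, Re_peak, alpha, label
    thresholds: tuple[float, float]

    def max_nonlaminar_generation(self) -> int | None:
        non = self.table[self.table["label"] != "laminar"]
        return None if non.empty else int(non["generation"].max())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def classify_regimes(
    tree: AirwayTree,
    result: SimulationResult,
    air: AirProperties = AirProperties(),
    settings: HFOVSettings = HFOVSettings(),
    thresholds: tuple[float, float] = DEFAULT_RE_THRESHOLDS,
    cycle: int | None = None,
) -> RegimeReport:
    """Label each segment laminar / transitional / turbulent_prone.

    The peak flow magnitude over one cycle (the detected steady-state cycle
    by default, else the final cycle) drives a peak-cycle Reynolds number;
    labels: Re >= upper -> turbulent_prone, lower <= Re < upper ->
    transitional, Re < lower -> laminar.
    """
    lo, hi = thresholds
    if not 0 < lo < hi:
        raise ValueError("thresholds must satisfy 0 < lower < upper")
    if cycle is None:
        cycle = (
            detect_steady_state(result) if result.n_cycles >= 2 else None
        ) or result.n_cycles
    sl = result.cycle_slice(cycle)
    idx = {sid: i for i, sid in enumerate(result.segment_ids)}
    rows = []
    for seg in tree.segments.values():
        q_peak = float(np.max(np.abs(result.segment_flows[idx[seg.id], sl])))
        re = reynolds_number(seg.diameter, q_peak, air)
        alpha = womersley_number(seg.diameter, settings.frequency, air)
        label = (
            "turbulent_prone" if re >= hi else "transitional" if re >= lo else "laminar"
        )
        rows.append(
            {
                "segment_id": seg.id,
                "generation": seg.generation,
                "Re_peak": re,
                "alpha": alpha,
                "label": label,
            }
        )
    return RegimeReport(table=pd.DataFrame(rows), thresholds=thresholds)


def leak_fraction(
    result: SimulationResult,
    tol_fraction_of_vt: float = 0.02,
) -> float:
    """Leak volume over one steady cycle divided by the supplied tidal volume.

    Uses the first steady-state cycle; if none is reached a warning is
    issued and the final cycle is used.  The leak volume is the trapezoidal
    integral of the recorded leak flow over the cycle.
    """
    cycle = (
        detect_steady_state(result, tol_fraction_of_vt)
        if result.n_cycles >= 2
        else None
    )
    if cycle is None:
        import warnings

        warnings.warn("no steady-state cycle detected; using the final cycle", stacklevel=2)
        cycle = result.n_cycles
    sl = result.cycle_slice(cycle)
    leak_volume = float(np.trapezoid(result.leak_flow[sl], result.times[sl]))
    return leak_volume / result.tidal_volume_abs


@dataclass
class RunSummary:
    """Headline observables of one pipeline run."""

    leak_fraction: float
    steady_state_cycle: int | None
    pendelluft_event_count: int
    direct_terminals: int
    delayed_terminals: int
    unreached_terminals: int
    dead_space_per_kg: float
    n_terminals: int
    re_thresholds: tuple[float, float]
    max_nonlaminar_generation: int | None

    def __post_init__(self) -> None:
        counts = self.direct_terminals + self.delayed_terminals + self.unreached_terminals
        if counts != self.n_terminals:
            raise ValueError(
                f"terminal classification counts ({counts}) do not sum to the "
                f"terminal count ({self.n_terminals})"
            )

    def to_json(self) -> str:
        d = asdict(self)
        d["re_thresholds"] = list(d["re_thresholds"])
        return json.dumps(d, indent=2, sort_keys=True)

    def render_text(self) -> str:
        lines = [
            "HFOV run summary",
            "----------------",
            f"anatomical dead space        : {self.dead_space_per_kg:.3f} ml/kg",
            f"tube leak fraction           : {100 * self.leak_fraction:.1f} % of supplied V_T",
            f"steady state reached         : cycle {self.steady_state_cycle}"
            if self.steady_state_cycle
            else "steady state reached         : not within the run",
            f"pendelluft event samples     : {self.pendelluft_event_count}",
            f"terminal oxygen delivery     : {self.direct_terminals} direct, "
            f"{self.delayed_terminals} delayed, {self.unreached_terminals} unreached "
            f"(of {self.n_terminals})",
            f"deepest non-laminar airway   : generation {self.max_nonlaminar_generation}"
            f" (Re thresholds {self.re_thresholds[0]:.0f}/{self.re_thresholds[1]:.0f})",
        ]
        return "\n".join(lines) + "\n"


def summarise_run(
    tree: AirwayTree,
    body_mass: float,
    result: SimulationResult,
    regime_report: RegimeReport,
    pendelluft_events: list,
    delivery: pd.DataFrame | None,
    leak_frac: float | None = None,
) -> RunSummary:
    """Aggregate all diagnostics into one deterministic summary."""
    missing = []
    if result is None:
        missing.append("flow simulation result")
    if regime_report is None:
        missing.append("regime report")
    if missing:
        raise ValueError(f"cannot summarise, missing inputs: {missing}")
    if delivery is None:
        counts = {"direct": 0, "delayed": 0, "unreached": len(tree.terminals())}
    else:
        vc = delivery["classification"].value_counts()
        counts = {k: int(vc.get(k, 0)) for k in ("direct", "delayed", "unreached")}
    return RunSummary(
        leak_fraction=leak_frac if leak_frac is not None else leak_fraction(result),
        steady_state_cycle=(
            detect_steady_state(result) if result.n_cycles >= 2 else None
        ),
        pendelluft_event_count=len(pendelluft_events),
        direct_terminals=counts["direct"],
        delayed_terminals=counts["delayed"],
        unreached_terminals=counts["unreached"],
        dead_space_per_kg=dead_space(tree, body_mass),
        n_terminals=len(tree.terminals()),
        re_thresholds=regime_report.thresholds,
        max_nonlaminar_generation=regime_report.max_nonlaminar_generation(),
    )
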