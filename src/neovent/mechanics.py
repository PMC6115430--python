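"""Respiratory mechanics: SOT estimation, regional lumped units, resistances.

The tissue beyond the resolved tree is represented per terminal outlet ``i``
by an equivalent downstream airway resistance R_eq^i (the unresolved
generations, by default 8-16, reduced by series/parallel composition of
laminar segment resistances) and a regional compliance C_eq^i (a share of
the total respiratory compliance C_rs measured by the single-occlusion
technique).  The pressure at the end of the resolved tree then closes the
network:

    P^i = R_eq^i Q^i + dV^i / C_eq^i,

with dV^i the time integral of the regional flow Q^i.  Pressures are stored
relative to the PEEP baseline, so dV^i is volume above the PEEP-equilibrated
FRC and the closure needs no offset term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .airway_tree import AirwaySegment, AirwayTree
from .synthetic_data import SOTManeuver
from .units import PA_S_PER_M3_TO_KPA_S_PER_ML

__all__ = [
    "AirProperties",
    "TerminalUnit",
    "MechanicsEstimate",
    "estimate_crs_sot",
    "partition_compliance",
    "poiseuille_resistance",
    "equivalent_downstream_resistance",
    "terminal_pressure",
    "build_terminal_units",
]


@dataclass(frozen=True)
class AirProperties:
    """Newtonian air at body conditions."""

    kinematic_viscosity: float = 17.0  # mm^2/s
    density: float = 1.27              # kg/m^3

    @property
    def dynamic_viscosity(self) -> float:
        """mu = rho * nu in Pa s."""
        return self.density * self.kinematic_viscosity * 1e-6


@dataclass(frozen=True)
class TerminalUnit:
    """Lumped R-C tissue unit behind one terminal outlet.

    State: volume above PEEP-equilibrated FRC ``delta_v`` (ml), last flow
    into the region ``flow`` (ml/s) and the closure pressure ``pressure``
    (kPa relative to PEEP).
    """

    outlet_id: str
    r_eq: float                  # kPa s/ml
    c_eq: float                  # ml/kPa
    delta_v: float = 0.0         # ml
    pressure: float = 0.0        # kPa (relative to PEEP)
    flow: float = 0.0            # ml/s

    def __post_init__(self) -> None:
        if self.c_eq <= 0:
            raise ValueError(f"{self.outlet_id}: c_eq must be positive")
        if self.r_eq < 0:
            raise ValueError(f"{self.outlet_id}: r_eq must be nonnegative")


@dataclass(frozen=True)
class MechanicsEstimate:
    """Result of fitting a single-occlusion maneuver."""

    crs: float            # ml/kPa
    resistance: float     # kPa s/ml
    time_constant: float  # s
    fit_diagnostics: dict

    def __post_init__(self) -> None:
        if self.crs <= 0 or self.resistance <= 0 or self.time_constant <= 0:
            raise ValueError("crs, resistance and time_constant must be positive")
        rel = abs(self.time_constant - self.resistance * self.crs) / self.time_constant
        if rel > 1e-6:
            raise ValueError(
                f"time_constant inconsistent with resistance*crs (rel err {rel:.2e})"
            )

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "crs_ml_per_kpa": self.crs,
                "resistance_kpa_s_per_ml": self.resistance,
                "time_constant_s": self.time_constant,
                "fit_diagnostics": self.fit_diagnostics,
            },
            indent=2,
            sort_keys=True,
        )


def estimate_crs_sot(maneuver: SOTManeuver) -> MechanicsEstimate:
    """Estimate C_rs, resistance and the expiratory time constant by SOT.

    Standard single-occlusion interpretation: total compliance is exhaled
    volume over occlusion plateau pressure; the time constant is the
    negative inverse slope of the (linear) flow-volume relation of passive
    expiration, fitted by least squares; resistance = tau / C_rs.  Because a
    finite recording never reaches zero flow, the exhaled volume is taken as
    the flow-volume line's extrapolated volume intercept (V0 = intercept *
    tau, the volume at which fitted flow crosses zero) — the usual SOT
    practice, exact for a noise-free single-compartment expiration of any
    duration.
    """
    if len(maneuver.time) < 10:
        raise ValueError("need at least 10 samples of passive expiration")
    if maneuver.plateau_pressure <= 0:
        raise ValueError("plateau pressure must be positive")
    volume = np.asarray(maneuver.volume, dtype=float)
    flow = np.asarray(maneuver.flow, dtype=float)
    # reject grossly non-monotone traces; noise-level local decreases are fine
    drawdown = np.max(np.maximum.accumulate(volume) - volume)
    if volume[-1] <= 0 or drawdown > 0.2 * np.max(volume):
        raise ValueError("volume is not a monotone exhaled-volume trace")
    # flow = (V0 - volume)/tau  =>  d(flow)/d(volume) = -1/tau
    slope, intercept = np.polyfit(volume, flow, 1)
    if slope >= 0:
        raise ValueError("flow-volume slope is nonnegative; not a passive expiration")
    tau = -1.0 / slope
    exhaled = intercept * tau  # extrapolated total exhaled volume V0
    crs = exhaled / maneuver.plateau_pressure
    resid = flow - (slope * volume + intercept)
    ss_tot = float(np.sum((flow - flow.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return MechanicsEstimate(
        crs=crs,
        resistance=tau / crs,
        time_constant=tau,
        fit_diagnostics={
            "n_samples": int(len(flow)),
            "r_squared": r2,
            "residual_sd_ml_s": float(np.std(resid)),
            "extrapolated_v0_ml": float(intercept * tau),
        },
    )


def partition_compliance(
    crs_total: float, tree: AirwayTree, weights: np.ndarray
) -> dict[str, float]:
    """Split C_rs over the terminal outlets: c_eq^i = w_i * C_rs.

    Regional compliances act in parallel, so the partition conserves the
    total exactly.  Terminal ordering is the tree's stored (depth-first)
    order, matching the heterogeneity generator.
    """
    if crs_total <= 0:
        raise ValueError("crs_total must be positive")
    terminals = tree.terminals()
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(terminals):
        raise ValueError(
            f"got {len(weights)} weights for {len(terminals)} terminal outlets"
        )
    if np.any(weights <= 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be positive and sum to 1")
    return {t.id: w * crs_total for t, w in zip(terminals, weights)}


def poiseuille_resistance(segment: AirwaySegment, air: AirProperties = AirProperties()) -> float:
    """Laminar (Hagen-Poiseuille) resistance of one segment, kPa s/ml.

    R = 128 mu L / (pi d^4), evaluated in SI and converted.
    """
    mu = air.dynamic_viscosity              # Pa s
    length_m = segment.length * 1e-3
    d_m = segment.diameter * 1e-3
    r_si = 128.0 * mu * length_m / (math.pi * d_m**4)  # Pa s / m^3
    return r_si * PA_S_PER_M3_TO_KPA_S_PER_ML


def equivalent_downstream_resistance(
    terminal_diameter: float,
    terminal_length: float,
    extra_generations: int = 9,
    diameter_ratio: float = 0.79,
    length_ratio: float = 0.79,
    air: AirProperties = AirProperties(),
) -> float:
    """Equivalent resistance of the unresolved subtree behind one outlet.

    A virtual symmetric dichotomous subtree continues the per-generation
    homothety for ``extra_generations`` further generations (default 9,
    i.e. generations 8-16 behind a generation-7 outlet) and is reduced by
    series/parallel composition: resistances add in series, conductances in
    parallel.  Recursion from the deepest level g:

        R_sub(g) = R_seg(g) + R_sub(g+1) / 2,    R_sub(G+1) = 0,

    and the outlet sees the two generation-(+1) subtrees in parallel,
    R_eq = R_sub(1) / 2.
    """
    if extra_generations < 1:
        raise ValueError("extra_generations must be at least 1")
    for name, r in (("diameter_ratio", diameter_ratio), ("length_ratio", length_ratio)):
        if not 0 < r < 1:
            raise ValueError(f"{name} must be in (0, 1), got {r}")
    r_sub = 0.0
    for g in range(extra_generations, 0, -1):
        seg = AirwaySegment(
            id=f"virtual_g{g}",
            parent_id=None,
            generation=g,
            length=terminal_length * length_ratio**g,
            diameter=terminal_diameter * diameter_ratio**g,
        )
        r_sub = poiseuille_resistance(seg, air) + r_sub / 2.0
    return r_sub / 2.0


def terminal_pressure(unit: TerminalUnit, q: float, dt: float) -> TerminalUnit:
    """Advance one lumped unit by ``dt`` under regional flow ``q``.

    Volume is integrated trapezoidally using the unit's stored previous
    flow; the closure pressure is R_eq q + dV/C_eq (relative to PEEP).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    delta_v = unit.delta_v + 0.5 * (unit.flow + q) * dt
    return replace(
        unit,
        delta_v=delta_v,
        flow=q,
        pressure=unit.r_eq * q + delta_v / unit.c_eq,
    )


def build_terminal_units(
    tree: AirwayTree,
    crs_total: float,
    weights: np.ndarray,
    air: AirProperties = AirProperties(),
    extra_generations: int = 9,
    diameter_ratio: float | None = None,
    length_ratio: float | None = None,
) -> dict[str, TerminalUnit]:
    """Construct the full terminal closure for a tree.

    Each outlet gets its compliance share and the equivalent resistance of
    its own unresolved subtree (continuing the tree's homothety ratios; if
    not given, ratios are inferred from the mean child/parent dimension
    ratio of the resolved tree).
    """
    if diameter_ratio is None or length_ratio is None:
        d_ratios, l_ratios = [], []
        for seg in tree.segments.values():
            if seg.parent_id is not None:
                parent = tree.segments[seg.parent_id]
                d_ratios.append(seg.diameter / parent.diameter)
                l_ratios.append(seg.length / parent.length)
        diameter_ratio = diameter_ratio or float(np.mean(d_ratios))
        length_ratio = length_ratio or float(np.mean(l_ratios))
    c_map = partition_compliance(crs_total, tree, weights)
    units: dict[str, TerminalUnit] = {}
    for term in tree.terminals():
        units[term.id] = TerminalUnit(
            outlet_id=term.id,
            r_eq=equivalent_downstream_resistance(
                term.diameter,
                term.length,
                extra_generations=extra_generations,
                diameter_ratio=diameter_ratio,
                length_ratio=length_ratio,
                air=air,
            ),
            c_eq=c_map[term.id],
        )
    return units


def compliance_map_to_csv(units: dict[str, TerminalUnit], path: str | Path) -> None:
    """Write the regional mechanics table (outlet_id, c_eq, r_eq)."""
    pd.DataFrame(
        {
            "outlet_id": list(units),
            "c_eq_ml_per_kPa": [u.c_eq for u in units.values()],
            "r_eq_kPa_s_per_ml": [u.r_eq for u in units.values()],
        }
    ).to_csv(path, index=False)
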