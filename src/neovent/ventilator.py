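"""HFOV ventilator boundary conditions and the uncuffed-tube leak.

The ventilator prescribes a half-sine inspiratory flow whose integral is the
set tidal volume, superimposed on a constant PEEP held at the proximal end
of the endotracheal tube; expiratory flow is not prescribed but develops
freely from regional lung mechanics against the PEEP.  Because neonatal
tubes are uncuffed, a leak path connects the tube opening (Y-piece) to
ambient; its size is not published for the modelled infant, so a linear
leak resistance is calibrated so that a stated fraction of the supplied
tidal volume (16% for the default run) escapes per cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mechanics import AirProperties, poiseuille_resistance
from .airway_tree import AirwaySegment
from .units import cmh2o_to_kpa

__all__ = [
    "HFOVSettings",
    "LeakModel",
    "TubeModel",
    "inspiratory_times",
    "flow_waveform",
    "leak_flow",
    "calibrate_leak",
]


@dataclass(frozen=True)
class HFOVSettings:
    """Ventilator prescription.  Defaults are the clinical settings of the
    modelled infant: f = 10 Hz, V_T = 2.0 ml/kg, I:E = 1:2, PEEP = 8 cmH2O,
    FiO2 = 0.35."""

    frequency: float = 10.0             # Hz
    tidal_volume_per_kg: float = 2.0    # ml/kg
    ie_ratio: tuple[float, float] = (1.0, 2.0)
    peep: float = 8.0                   # cmH2O (converted via .peep_kpa)
    fio2: float = 0.35                  # volume fraction in (0, 1]
    n_cycles: int = 6

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.tidal_volume_per_kg <= 0:
            raise ValueError("frequency and tidal volume must be positive")
        i, e = self.ie_ratio
        if i <= 0 or e <= 0:
            raise ValueError("I:E components must be positive")
        if not 0 < self.fio2 <= 1:
            raise ValueError("fio2 must be in (0, 1]")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")

    @property
    def peep_kpa(self) -> float:
        return cmh2o_to_kpa(self.peep)

    def tidal_volume_abs(self, body_mass: float) -> float:
        """Absolute tidal volume in ml."""
        return self.tidal_volume_per_kg * body_mass


@dataclass(frozen=True)
class LeakModel:
    """Leak path between Y-piece and ambient.

    Exactly one of ``resistance`` (linear regime, kPa s/ml) or
    ``orifice_area`` (orifice regime, mm^2) is set, matching ``regime``.
    """

    regime: str = "linear"
    resistance: float | None = None
    orifice_area: float | None = None

    def __post_init__(self) -> None:
        if self.regime == "linear":
            if self.resistance is None or self.orifice_area is not None:
                raise ValueError("linear leak needs resistance only")
            if self.resistance <= 0:
                raise ValueError("leak resistance must be positive")
        elif self.regime == "orifice":
            if self.orifice_area is None or self.resistance is not None:
                raise ValueError("orifice leak needs orifice_area only")
            if self.orifice_area <= 0:
                raise ValueError("orifice area must be positive")
        else:
            raise ValueError(f"unknown leak regime {self.regime!r}")


@dataclass(frozen=True)
class TubeModel:
    """Endotracheal tube: default uncuffed 3.0 mm inner diameter.

    The tube length is a declared default (100 mm, a typical neonatal oral
    tube); resistance is laminar on the cylinder.
    """

    inner_diameter: float = 3.0  # mm
    length: float = 100.0        # mm

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0 or self.length <= 0:
            raise ValueError("tube dimensions must be positive")

    def resistance(self, air: AirProperties = AirProperties()) -> float:
        seg = AirwaySegment(
            id="ETT", parent_id=None, generation=0,
            length=self.length, diameter=self.inner_diameter,
        )
        return poiseuille_resistance(seg, air)


def inspiratory_times(settings: HFOVSettings) -> tuple[float, float, float]:
    """(period, t_insp, t_exp) in seconds from frequency and I:E."""
    period = 1.0 / settings.frequency
    i, e = settings.ie_ratio
    t_insp = period * i / (i + e)
    return period, t_insp, period - t_insp


def flow_waveform(settings: HFOVSettings, body_mass: float, t) -> np.ndarray | float:
    """Prescribed source flow at the Y-piece (ml/s) at time(s) ``t``.

    Half-sine during inspiration, Q(t) = Q_peak sin(pi t / t_insp) with
    Q_peak = pi V_T_abs / (2 t_insp) so the inspiratory integral equals the
    absolute tidal volume; zero during expiration (flow develops freely).
    Times are reduced modulo the cycle period.
    """
    period, t_insp, _ = inspiratory_times(settings)
    vt = settings.tidal_volume_abs(body_mass)
    q_peak = math.pi * vt / (2.0 * t_insp)
    tm = np.mod(np.asarray(t, dtype=float), period)
    q = np.where(tm < t_insp, q_peak * np.sin(math.pi * tm / t_insp), 0.0)
    return float(q) if np.isscalar(t) else q


def leak_flow(
    leak: LeakModel, p_opening: float, air: AirProperties = AirProperties()
) -> float:
    """Leak flow (ml/s, positive out of the circuit) at opening pressure
    ``p_opening`` (kPa relative to ambient).

    Linear regime: Q = p / R_leak.  Orifice regime: Q = sign(p) A
    sqrt(2 |p| / rho).  Because PEEP keeps the opening pressure positive,
    leak flows in both phases.
    """
    if leak.regime == "linear":
        return p_opening / leak.resistance
    # orifice: A [mm^2 -> m^2], p [kPa -> Pa], rho [kg/m^3]; Q [m^3/s -> ml/s]
    v = math.sqrt(2.0 * abs(p_opening) * 1e3 / air.density)
    return math.copysign(leak.orifice_area * 1e-6 * v * 1e6, p_opening)


def calibrate_leak(
    leak_fraction_of_resistance,
    target_leak_fraction: float,
    bracket: tuple[float, float] = (1e-3, 1e2),
    tol: float = 0.005,
    max_iter: int = 60,
) -> tuple[LeakModel, float]:
    """Calibrate a linear leak resistance to a target per-cycle leak fraction.

    ``leak_fraction_of_resistance`` is a pipeline handle: a callable mapping
    a linear leak resistance (kPa s/ml) to the simulated leak fraction of
    the supplied tidal volume.  The fraction is monotone decreasing in the
    resistance, so bisection on log-resistance converges; iteration stops
    when the achieved fraction is within ``tol`` (absolute, default 0.5
    percentage points) of the target.

    The image-derived leak area of the modelled infant is unpublished; the
    published ~16% leak fraction is therefore a calibration anchor, not an
    independent prediction.
    """
    if not 0 < target_leak_fraction < 1:
        raise ValueError("target leak fraction must be in (0, 1)")
    lo, hi = bracket
    f_lo = leak_fraction_of_resistance(lo)   # small R -> large fraction
    f_hi = leak_fraction_of_resistance(hi)
    if not (f_hi <= target_leak_fraction <= f_lo):
        raise ValueError(
            f"target {target_leak_fraction} not bracketed: fraction({lo})={f_lo:.4f}, "
            f"fraction({hi})={f_hi:.4f}"
        )
    achieved, r_mid = f_lo, lo
    for _ in range(max_iter):
        r_mid = math.sqrt(lo * hi)
        achieved = leak_fraction_of_resistance(r_mid)
        if abs(achieved - target_leak_fraction) < tol:
            break
        if achieved > target_leak_fraction:
            lo = r_mid
        else:
            hi = r_mid
    else:
        raise ValueError(
            f"calibration did not reach target {target_leak_fraction} within "
            f"bracket {bracket}; last fraction {achieved:.4f}"
        )
    return LeakModel(regime="linear", resistance=r_mid), achieved
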