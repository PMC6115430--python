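"""Synthetic inputs for the HFOV pipeline.

No public dataset exists for the clinical side of this problem: MRI-derived
airway geometry and infant lung function testing (ILFT) traces of individual
preterm infants are not deposited.  Everything the pipeline consumes is
therefore generated here with the physiological structure the downstream
stages assume:

* a patient fixture carrying the published characteristics of the modelled
  infant (birth weight 0.76 kg, total respiratory compliance
  C_rs = 20.93 ml/kPa, BPD grade 3, 27.3 weeks gestation);
* single-occlusion-technique (SOT) maneuvers — passive exponential
  expiration against an occlusion plateau — from which compliance and
  resistance are re-estimated by :mod:`neovent.mechanics`;
* regional compliance weight maps mimicking the patchy mechanics of
  bronchopulmonary dysplasia (BPD).

All generators are pure functions of their parameters and an explicit seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "PatientFixture",
    "SOTManeuver",
    "make_patient",
    "make_sot_maneuver",
    "make_compliance_heterogeneity",
]


@dataclass(frozen=True)
class PatientFixture:
    """Characteristics of the ventilated infant.

    Defaults are the modelled patient: an extremely preterm infant
    (27.3 weeks postmenstrual age, birth weight 760 g) with severe (grade 3)
    bronchopulmonary dysplasia and a total respiratory system compliance of
    20.93 ml/kPa measured by the single-occlusion technique.  The
    plethysmographic functional residual capacity is not publicly reported
    and is stored as ``None`` (unknown).
    """

    body_mass: float = 0.76          # kg
    crs_total: float = 20.93         # ml/kPa
    frc: float | None = None         # ml, unknown for the default patient
    bpd_grade: int = 3               # 0 (none) .. 3 (severe)
    gestational_age: float = 27.3    # weeks PMA

    def __post_init__(self) -> None:
        if not self.body_mass > 0:
            raise ValueError(f"body_mass must be positive, got {self.body_mass}")
        if not self.crs_total > 0:
            raise ValueError(f"crs_total must be positive, got {self.crs_total}")
        if self.frc is not None and self.frc < 0:
            raise ValueError(f"frc must be nonnegative, got {self.frc}")
        if not 0 <= int(self.bpd_grade) <= 3:
            raise ValueError(f"bpd_grade must be in 0..3, got {self.bpd_grade}")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PatientFixture":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


def make_patient(overrides: dict | None = None) -> PatientFixture:
    """Build a patient fixture, defaulting to the modelled preterm infant."""
    return PatientFixture(**(overrides or {}))


@dataclass(frozen=True)
class SOTManeuver:
    """A single-occlusion-technique trace.

    ``flow`` is expiratory flow (positive out of the lung, ml/s), ``volume``
    the running exhaled volume (ml, the trapezoidal integral of ``flow``),
    and ``plateau_pressure`` the airway-opening pressure during the brief
    occlusion (kPa above atmosphere).
    """

    time: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    plateau_pressure: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time must be a strictly increasing 1-d vector")
        if not self.plateau_pressure > 0:
            raise ValueError("plateau_pressure must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.time, "flow_ml_s": self.flow, "volume_ml": self.volume}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, plateau_pressure: float) -> "SOTManeuver":
        df = pd.read_csv(path)
        return cls(
            time=df["time_s"].to_numpy(),
            flow=df["flow_ml_s"].to_numpy(),
            volume=df["volume_ml"].to_numpy(),
            plateau_pressure=plateau_pressure,
        )


def make_sot_maneuver(
    patient: PatientFixture,
    resistance: float,
    occlusion_volume: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = 501,
    duration_time_constants: float = 5.0,
) -> SOTManeuver:
    """Generate a passive-expiration SOT trace for ``patient``.

    The single-compartment signal model: after release of a brief airway
    occlusion holding ``occlusion_volume`` above relaxation volume, the lung
    empties passively through total resistance R with time constant
    tau = R * C_rs, so

        flow(t) = (V0 / tau) * exp(-t / tau),
        plateau_pressure = V0 / C_rs.

    Gaussian noise of standard deviation ``noise_sd`` (ml/s) is added to the
    flow channel; the volume channel is the trapezoidal integral of the
    noisy flow, as a real pneumotachograph-based system would integrate.
    """
    if resistance <= 0 or occlusion_volume <= 0:
        raise ValueError("resistance and occlusion_volume must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    tau = resistance * patient.crs_total
    t = np.linspace(0.0, duration_time_constants * tau, n_samples)
    flow = (occlusion_volume / tau) * np.exp(-t / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        flow = flow + rng.normal(0.0, noise_sd, size=flow.shape)
    volume = cumulative_trapezoid(flow, t, initial=0.0)
    return SOTManeuver(
        time=t,
        flow=flow,
        volume=volume,
        plateau_pressure=occlusion_volume / patient.crs_total,
        noise_sd=noise_sd,
    )


def make_compliance_heterogeneity(
    n_terminals: int,
    profile: str = "uniform",
    severity: float = 0.5,
    seed: int = 0,
    patch_fraction: float = 0.25,
) -> np.ndarray:
    """Regional compliance weights over the terminal outlets.

    ``uniform`` returns equal weights.  ``bpd_patchy`` emulates BPD-affected
    tissue: a seeded, contiguous block of ``patch_fraction`` of the terminals
    (anatomically neighbouring regions under the depth-first terminal
    ordering) has its weight reduced by the factor ``1 - severity``, after
    which all weights are renormalised to sum to one.  ``severity = 0``
    degenerates to the uniform profile.
    """
    if n_terminals < 2:
        raise ValueError("n_terminals must be at least 2")
    if not 0 <= severity < 1:
        raise ValueError(f"severity must be in [0, 1), got {severity}")
    w = np.full(n_terminals, 1.0 / n_terminals)
    if profile == "uniform":
        return w
    if profile != "bpd_patchy":
        raise ValueError(f"unknown profile {profile!r}")
    patch_size = max(1, int(round(patch_fraction * n_terminals)))
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, n_terminals - patch_size + 1))
    w[start : start + patch_size] *= 1.0 - severity
    return w / w.sum()
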