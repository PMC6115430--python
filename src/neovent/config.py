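"""Pipeline configuration: defaults, validation, unit normalisation.

A single YAML or JSON file drives the whole pipeline.  An empty file yields
the full default configuration (the modelled patient on the clinical HFOV
settings: f = 10 Hz, V_T = 2.0 ml/kg, I:E = 1:2, PEEP = 8 cmH2O,
FiO2 = 0.35).  Unknown keys are rejected by name; clinical units (cmH2O for
PEEP) are converted at this boundary only.  Internal units are kPa, ml, s,
mm throughout.

The single global seed fans out deterministically to the per-stage seeds
(tree jitter, compliance heterogeneity, SOT noise) via
``numpy.random.SeedSequence(seed).generate_state``, so every stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .units import cmh2o_to_kpa

__all__ = ["PipelineConfig", "load_config", "derive_seeds"]


@dataclass
class PatientConfig:
    body_mass: float = 0.76         # kg
    crs_total: float = 20.93        # ml/kPa
    bpd_grade: int = 3
    gestational_age: float = 27.3   # weeks


@dataclass
class MorphometryConfig:
    trachea_length: float = 30.0
    trachea_diameter: float = 3.5
    diameter_ratio_per_generation: float = 0.79
    length_ratio_per_generation: float = 0.79
    asymmetry_factor: float = 0.1
    jitter_sd: float = 0.0
    max_generation: int = 7
    target_deadspace_per_kg: float = 2.2  # ml/kg


@dataclass
class MechanicsConfig:
    partition_profile: str = "bpd_patchy"  # or "uniform"
    severity: float = 0.5
    patch_fraction: float = 0.25
    sot_resistance: float = 0.005          # kPa s/ml, maneuver generator
    sot_occlusion_volume: float = 10.0     # ml
    sot_noise_sd: float = 0.0              # ml/s
    downstream_generations: int = 9        # generations 8-16


@dataclass
class VentilatorConfig:
    frequency: float = 10.0
    tidal_volume_per_kg: float = 2.0
    ie_ratio: list = field(default_factory=lambda: [1.0, 2.0])
    peep: float | str = 8.0                 # cmH2O, or a string like "8 cmH2O"
    fio2: float = 0.35
    n_cycles: int = 6
    tube_inner_diameter: float = 3.0        # mm
    tube_length: float = 100.0              # mm
    leak_mode: str = "calibrate"            # calibrate | linear | orifice | none
    leak_target_fraction: float = 0.16
    leak_resistance: float | None = None    # kPa s/ml (linear mode)
    leak_orifice_area: float | None = None  # mm^2 (orifice mode)


@dataclass
class SolverConfig:
    dt: float | None = None     # s; default t_insp/200
    inertance: bool = False
    trachea_nonlinearity_factor: float = 1.0
    steady_state_tol: float = 0.02          # fraction of V_T
    pendelluft_threshold: float = 0.02      # fraction of peak inlet flow


@dataclass
class TransportConfig:
    diffusivity: float = 0.219   # cm^2/s
    cells_per_segment: int = 20
    initial_concentration: float = 0.21
    arrival_threshold: float = 0.25
    n_cycles: int | None = None  # default: all flow cycles
    enabled: bool = True


@dataclass
class OutputConfig:
    snapshot_stride: int = 0     # 0 = no field snapshots
    flow_stride: int = 5         # stride for the long-format flow export


@dataclass
class PipelineConfig:
    patient: PatientConfig = field(default_factory=PatientConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    mechanics: MechanicsConfig = field(default_factory=MechanicsConfig)
    ventilator: VentilatorConfig = field(default_factory=VentilatorConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    transport: TransportConfig = field(default_factory=TransportConfig)
    output: OutputConfig = field(default_factory=OutputConfig)
    seed: int = 0

    @property
    def peep_cmh2o(self) -> float:
        return _parse_pressure_cmh2o(self.ventilator.peep, "ventilator.peep")

    @property
    def peep_kpa(self) -> float:
        return cmh2o_to_kpa(self.peep_cmh2o)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ventilator"]["peep"] = self.peep_cmh2o
        return d

    def echo_json(self) -> str:
        """Canonical JSON of the effective configuration (units normalised)."""
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.echo_json().encode()).hexdigest()[:16]


def _parse_pressure_cmh2o(value, where: str) -> float:
    """Accept a bare number (cmH2O) or '<number> cmH2O' / '<number> kPa'."""
    if isinstance(value, (int, float)):
        return float(value)
    parts = str(value).split()
    if len(parts) != 2:
        raise ValueError(f"{where}: cannot parse pressure {value!r}")
    num, unit = parts
    try:
        x = float(num)
    except ValueError:
        raise ValueError(f"{where}: cannot parse pressure {value!r}") from None
    unit_l = unit.lower()
    if unit_l in ("cmh2o", "cm_h2o"):
        return x
    if unit_l == "kpa":
        return x / cmh2o_to_kpa(1.0)
    raise ValueError(f"{where}: unknown pressure unit suffix {unit!r}")


def _merge(dc, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(dc)}
    for key, value in data.items():
        if key not in names:
            raise ValueError(f"unknown configuration key {path}{key!r}")
        current = getattr(dc, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _merge(current, value, f"{path}{key}.")
        else:
            setattr(dc, key, value)


def load_config(source: str | Path | dict | None = None) -> PipelineConfig:
    """Load and validate a pipeline configuration.

    ``source`` may be a YAML/JSON path, an already-parsed mapping, or None /
    an empty file for the full defaults.  Unknown keys raise by name.
    """
    cfg = PipelineConfig()
    if source is None:
        data: dict = {}
    elif isinstance(source, dict):
        data = source
    else:
        text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{source}: top level must be a mapping")
    _merge(cfg, data, "")
    _validate(cfg)
    return cfg


def _validate(cfg: PipelineConfig) -> None:
    if cfg.patient.body_mass <= 0 or cfg.patient.crs_total <= 0:
        raise ValueError("patient.body_mass and patient.crs_total must be positive")
    cfg.peep_kpa  # raises on malformed pressure strings
    if cfg.ventilator.leak_mode not in ("calibrate", "linear", "orifice", "none"):
        raise ValueError(f"ventilator.leak_mode: unknown mode {cfg.ventilator.leak_mode!r}")
    if cfg.ventilator.leak_mode == "linear" and not cfg.ventilator.leak_resistance:
        raise ValueError("ventilator.leak_resistance required for leak_mode 'linear'")
    if cfg.ventilator.leak_mode == "orifice" and not cfg.ventilator.leak_orifice_area:
        raise ValueError("ventilator.leak_orifice_area required for leak_mode 'orifice'")
    if not 0 <= cfg.mechanics.severity < 1:
        raise ValueError("mechanics.severity must be in [0, 1)")
    if cfg.mechanics.partition_profile not in ("uniform", "bpd_patchy"):
        raise ValueError(
            f"mechanics.partition_profile: unknown profile "
            f"{cfg.mechanics.partition_profile!r}"
        )
    if not 0 < cfg.ventilator.fio2 <= 1:
        raise ValueError("ventilator.fio2 must be in (0, 1]")


def derive_seeds(seed: int) -> dict[str, int]:
    """Fan the global seed out to independent per-stage seeds (< 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(3)
    names = ("tree_jitter", "heterogeneity", "sot_noise")
    return {n: int(s % (2**31)) for n, s in zip(names, state)}
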