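"""End-to-end pipeline: fixtures -> tree -> mechanics -> flow -> oxygen -> report.

Stages run in a fixed order and every artefact is written under one output
directory together with the echoed effective configuration and its hash, so
reruns with the same configuration are reproducible.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

from . import airway_tree as at
from . import diagnostics as dg
from . import flow_solver as fs
from . import gas_transport as gt
from . import mechanics as mech
from . import synthetic_data as sd
from . import ventilator as vent
from .config import PipelineConfig, derive_seeds, load_config

__all__ = ["PipelineArtifacts", "build_model", "run_pipeline"]


@dataclass
class PipelineArtifacts:
    """Everything a run produces, in memory."""

    config: PipelineConfig
    patient: sd.PatientFixture
    tree: at.AirwayTree
    units: dict[str, mech.TerminalUnit]
    settings: vent.HFOVSettings
    tube: vent.TubeModel
    leak: vent.LeakModel | None
    leak_achieved: float | None
    result: fs.SimulationResult | None = None
    gas: gt.GasHistory | None = None
    delivery: object | None = None
    summary: dg.RunSummary | None = None
    timings: dict = field(default_factory=dict)


def _settings_from(cfg: PipelineConfig) -> vent.HFOVSettings:
    v = cfg.ventilator
    return vent.HFOVSettings(
        frequency=v.frequency,
        tidal_volume_per_kg=v.tidal_volume_per_kg,
        ie_ratio=tuple(v.ie_ratio),
        peep=cfg.peep_cmh2o,
        fio2=v.fio2,
        n_cycles=v.n_cycles,
    )


def build_model(cfg: PipelineConfig | None = None) -> PipelineArtifacts:
    """Build patient, tree, terminal units, ventilator and (calibrated) leak."""
    cfg = cfg or load_config(None)
    seeds = derive_seeds(cfg.seed)
    patient = sd.make_patient(
        {
            "body_mass": cfg.patient.body_mass,
            "crs_total": cfg.patient.crs_total,
            "bpd_grade": cfg.patient.bpd_grade,
            "gestational_age": cfg.patient.gestational_age,
        }
    )
    m = cfg.morphometry
    params = at.MorphometryParams(
        trachea_length=m.trachea_length,
        trachea_diameter=m.trachea_diameter,
        diameter_ratio_per_generation=m.diameter_ratio_per_generation,
        length_ratio_per_generation=m.length_ratio_per_generation,
        asymmetry_factor=m.asymmetry_factor,
        jitter_sd=m.jitter_sd,
        seed=seeds["tree_jitter"],
        max_generation=m.max_generation,
    )
    tree = at.generate_tree(params, patient.body_mass, m.target_deadspace_per_kg)
    weights = sd.make_compliance_heterogeneity(
        n_terminals=len(tree.terminals()),
        profile=cfg.mechanics.partition_profile,
        severity=cfg.mechanics.severity,
        seed=seeds["heterogeneity"],
        patch_fraction=cfg.mechanics.patch_fraction,
    )
    units = mech.build_terminal_units(
        tree,
        patient.crs_total,
        weights,
        extra_generations=cfg.mechanics.downstream_generations,
        diameter_ratio=m.diameter_ratio_per_generation,
        length_ratio=m.length_ratio_per_generation,
    )
    settings = _settings_from(cfg)
    tube = vent.TubeModel(
        inner_diameter=cfg.ventilator.tube_inner_diameter,
        length=cfg.ventilator.tube_length,
    )

    leak: vent.LeakModel | None
    achieved: float | None = None
    mode = cfg.ventilator.leak_mode
    if mode == "none":
        leak = None
    elif mode == "linear":
        leak = vent.LeakModel(regime="linear", resistance=cfg.ventilator.leak_resistance)
    elif mode == "orifice":
        leak = vent.LeakModel(
            regime="orifice", orifice_area=cfg.ventilator.leak_orifice_area
        )
    else:  # calibrate

        def fraction_of(resistance: float) -> float:
            trial = vent.LeakModel(regime="linear", resistance=resistance)
            res = fs.simulate(
                tree, units, tube, trial, settings, patient.body_mass,
                dt=cfg.solver.dt, n_cycles=settings.n_cycles,
                trachea_nonlinearity_factor=cfg.solver.trachea_nonlinearity_factor,
            )
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return dg.leak_fraction(res, cfg.solver.steady_state_tol)

        leak, achieved = vent.calibrate_leak(
            fraction_of, cfg.ventilator.leak_target_fraction
        )
    return PipelineArtifacts(
        config=cfg,
        patient=patient,
        tree=tree,
        units=units,
        settings=settings,
        tube=tube,
        leak=leak,
        leak_achieved=achieved,
    )


def run_pipeline(
    cfg: PipelineConfig | str | Path | None = None,
    outdir: str | Path | None = None,
) -> PipelineArtifacts:
    """Execute all stages; write artefacts under ``outdir`` if given."""
    if not isinstance(cfg, PipelineConfig):
        cfg = load_config(cfg)
    timings: dict[str, float] = {}

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = _time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = _time.perf_counter() - self.t0

        return _T()

    try:
        with timed("build_model"):
            art = build_model(cfg)
    except Exception as exc:
        raise RuntimeError(f"stage build_model failed: {exc}") from exc
    art.timings = timings

    with timed("flow_solver"):
        art.result = fs.simulate(
            art.tree, art.units, art.tube, art.leak, art.settings,
            art.patient.body_mass,
            dt=cfg.solver.dt,
            inertance=cfg.solver.inertance,
            trachea_nonlinearity_factor=cfg.solver.trachea_nonlinearity_factor,
        )
    events = fs.detect_pendelluft(art.result, art.tree, cfg.solver.pendelluft_threshold)

    if cfg.transport.enabled:
        with timed("gas_transport"):
            params = gt.TransportParams(
                diffusivity=cfg.transport.diffusivity,
                inlet_concentration=cfg.ventilator.fio2,
                cells_per_segment=cfg.transport.cells_per_segment,
                initial_concentration=cfg.transport.initial_concentration,
            )
            art.gas = gt.simulate_transport(
                art.result, art.tree, params,
                n_cycles=cfg.transport.n_cycles,
                snapshot_stride=cfg.output.snapshot_stride or None,
            )
            art.delivery = gt.oxygen_delivery_metrics(
                art.gas, art.tree, cfg.transport.arrival_threshold
            )

    with timed("diagnostics"):
        regimes = dg.classify_regimes(
            art.tree, art.result, settings=art.settings
        )
        art.summary = dg.summarise_run(
            art.tree,
            art.patient.body_mass,
            art.result,
            regimes,
            events,
            art.delivery,
            leak_frac=art.leak_achieved,
        )

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config_effective.json").write_text(cfg.echo_json() + "\n")
        at.write_tree(art.tree, out / "tree.csv")
        mech.compliance_map_to_csv(art.units, out / "mechanics.csv")
        art.result.to_long_frame(stride=max(1, cfg.output.flow_stride)).to_csv(
            out / "flows_long.csv", index=False
        )
        if art.gas is not None:
            gt.oxygen_budget(art.gas).to_csv(out / "oxygen_budget.csv", index=False)
            art.delivery.to_csv(out / "oxygen_delivery.csv", index=False)
            if art.gas.final_field is not None:
                art.gas.final_field.to_frame().to_csv(
                    out / "gas_field_final.csv", index=False
                )
        regimes.to_csv(out / "regimes.csv")
        (out / "run_summary.json").write_text(art.summary.to_json() + "\n")
        (out / "run_summary.txt").write_text(art.summary.render_text())
        log = {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "derived_seeds": derive_seeds(cfg.seed),
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "leak_achieved_fraction": art.leak_achieved,
            "pendelluft_events": len(events),
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return art
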