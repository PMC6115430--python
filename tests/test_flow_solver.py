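"""Network solver: oracle equivalence, conservation, symmetry, detection ops."""

import math

import numpy as np
import pytest

import neovent as nv
from conftest import single_compartment_model


def closed_form_single_compartment(times, settings, body_mass, r_total, c_eq):
    """Piecewise closed-form volume of one R-C compartment under HFOV:
    prescribed half-sine inflow (volume independent of mechanics), passive
    exponential relaxation toward the PEEP baseline during expiration."""
    period, t_insp, t_exp = nv.inspiratory_times(settings)
    vt = settings.tidal_volume_abs(body_mass)
    tau = r_total * c_eq
    v = np.empty_like(times)
    v_start = 0.0  # volume at cycle start
    for i, t in enumerate(times):
        k = min(int(t / period + 1e-12), 10**6)
        tm = t - k * period
        if tm < 0:
            k -= 1
            tm = t - k * period
        # recompute cycle-start volume by recursion
        v_n = 0.0
        for _ in range(k):
            v_n = (v_n + vt) * math.exp(-t_exp / tau)
        if tm <= t_insp + 1e-15:
            v[i] = v_n + vt / 2.0 * (1.0 - math.cos(math.pi * tm / t_insp))
        else:
            v[i] = (v_n + vt) * math.exp(-(tm - t_insp) / tau)
    return v


class TestOracleEquivalence:
    def test_matches_closed_form_rc_response(self):
        """Max relative error < 1e-3 against the analytic single-compartment
        solution at dt = t_insp / 200."""
        tree, units, tube = single_compartment_model(r_eq=0.002, c_eq=20.93)
        settings = nv.HFOVSettings(n_cycles=3)
        result = nv.simulate(tree, units, tube, None, settings, 0.76)
        r_total = (
            tube.resistance()
            + nv.poiseuille_resistance(tree.root)
            + units["T"].r_eq
        )
        expected = closed_form_single_compartment(
            result.times, settings, 0.76, r_total, units["T"].c_eq
        )
        err = np.max(np.abs(result.lung_volume_above_frc - expected))
        assert err / np.max(np.abs(expected)) < 1e-3

    def test_expiratory_inlet_flow_matches_rc_relaxation(self):
        tree, units, tube = single_compartment_model(r_eq=0.002, c_eq=20.93)
        settings = nv.HFOVSettings(n_cycles=2)
        result = nv.simulate(tree, units, tube, None, settings, 0.76)
        r_total = tube.resistance() + nv.poiseuille_resistance(tree.root) + units["T"].r_eq
        tau = r_total * units["T"].c_eq
        # mid-expiration of cycle 2
        _, t_insp, t_exp = nv.inspiratory_times(settings)
        t_probe = 1.0 / settings.frequency + t_insp + 0.5 * t_exp
        i = np.argmin(np.abs(result.times - t_probe))
        v_here = result.lung_volume_above_frc[i]
        assert result.inlet_flow[i] == pytest.approx(-v_here / tau, rel=2e-2)


class TestConservationAndSymmetry:
    def test_rest_state_is_a_fixed_point(self, default_artifacts):
        a = default_artifacts
        _, t_insp, t_exp = nv.inspiratory_times(a.settings)
        state = nv.NetworkState(
            time=t_insp + 0.25 * t_exp,
            segment_flows={s: 0.0 for s in a.tree.segments},
            nodal_pressures={},
            terminal_units=a.units,
        )
        new = nv.assemble_and_step(
            state, a.tree, a.units, a.tube, None, a.settings,
            a.patient.body_mass, dt=1e-4,
        )
        assert all(abs(q) < 1e-12 for q in new.segment_flows.values())
        assert all(abs(p) < 1e-12 for p in new.nodal_pressures.values())
        assert all(u.delta_v == 0.0 for u in new.terminal_units.values())

    def test_symmetric_two_terminal_split_is_exactly_half(self):
        segs = {
            "T": nv.AirwaySegment("T", None, 0, 27.0, 3.2),
            "TL": nv.AirwaySegment("TL", "T", 1, 21.0, 2.5, is_terminal=True),
            "TR": nv.AirwaySegment("TR", "T", 1, 21.0, 2.5, is_terminal=True),
        }
        tree = nv.AirwayTree(segments=segs, root_id="T")
        units = {
            t: nv.TerminalUnit(t, r_eq=0.05, c_eq=10.0) for t in ("TL", "TR")
        }
        result = nv.simulate(
            tree, units, nv.TubeModel(), None, nv.HFOVSettings(n_cycles=2), 0.76
        )
        i_l = result.segment_ids.index("TL")
        i_r = result.segment_ids.index("TR")
        np.testing.assert_allclose(
            result.segment_flows[i_l], result.segment_flows[i_r], atol=1e-12
        )
        i_t = result.segment_ids.index("T")
        np.testing.assert_allclose(
            result.segment_flows[i_t],
            2 * result.segment_flows[i_l],
            atol=1e-10,
        )

    def test_volume_closure_at_machine_tolerance(self, default_result):
        r = default_result
        residual = (
            r.cumulative_inlet_volume
            - r.cumulative_leak_volume
            - r.lung_volume_above_frc
        )
        assert np.max(np.abs(residual)) < 1e-9 * r.tidal_volume_abs

    def test_interior_nodes_conserve_flow(self, default_result, default_artifacts):
        r = default_result
        tree = default_artifacts.tree
        idx = {sid: i for i, sid in enumerate(r.segment_ids)}
        peak = np.max(np.abs(r.inlet_flow))
        for parent in tree.segments.values():
            kids = tree.children(parent.id)
            if len(kids) != 2:
                continue
            gap = r.segment_flows[idx[parent.id]] - (
                r.segment_flows[idx[kids[0].id]] + r.segment_flows[idx[kids[1].id]]
            )
            assert np.max(np.abs(gap)) < 1e-9 * peak

    def test_halving_dt_converges(self, default_artifacts):
        a = default_artifacts
        _, t_insp, _ = nv.inspiratory_times(a.settings)
        kw = dict(n_cycles=2)
        r1 = nv.simulate(a.tree, a.units, a.tube, a.leak, a.settings,
                         a.patient.body_mass, dt=t_insp / 200, **kw)
        r2 = nv.simulate(a.tree, a.units, a.tube, a.leak, a.settings,
                         a.patient.body_mass, dt=t_insp / 400, **kw)
        eev1 = r1.end_expiratory_volumes()[-1]
        eev2 = r2.end_expiratory_volumes()[-1]
        assert abs(eev1 - eev2) / eev2 < 0.005


def _fake_result(eev_by_cycle, vt=1.52, steps_per_cycle=10):
    """Minimal SimulationResult carrying a prescribed end-expiratory-volume
    sequence, for testing the steady-state detector in isolation."""
    n_cycles = len(eev_by_cycle)
    n = n_cycles * steps_per_cycle
    lung = np.zeros(n + 1)
    bounds = np.arange(0, n + 1, steps_per_cycle)
    for k, v in enumerate(eev_by_cycle):
        lung[bounds[k + 1]] = v
    z = np.zeros(n + 1)
    return nv.SimulationResult(
        times=np.linspace(0, 0.1 * n_cycles, n + 1),
        inlet_flow=z, source_flow=z, leak_flow=z,
        lung_volume_above_frc=lung,
        terminal_volumes=np.zeros((1, n + 1)),
        segment_flows=np.zeros((1, n + 1)),
        segment_ids=["T"], terminal_ids=["T"],
        cycle_bounds=bounds, tidal_volume_abs=vt,
        dt_insp=1e-3, dt_exp=1e-3,
        cumulative_inlet_volume=z, cumulative_leak_volume=z,
    )


class TestSteadyStateDetection:
    def test_already_periodic_detected_at_first_comparable_cycle(self):
        r = _fake_result([2.0, 2.0, 2.0, 2.0])
        assert nv.detect_steady_state(r, 0.02) == 2

    def test_zero_tolerance_never_detects(self):
        r = _fake_result([2.0, 2.0, 2.0])
        assert nv.detect_steady_state(r, 0.0) is None

    def test_detects_first_cycle_below_tolerance(self):
        # diffs: 0.5, 0.2, 0.02, 0.01; tol 0.02*1.52 = 0.0304 -> cycle 4
        r = _fake_result([1.0, 1.5, 1.7, 1.72, 1.73])
        assert nv.detect_steady_state(r, 0.02) == 4


class TestPendelluft:
    def test_symmetric_homogeneous_lung_shows_none(self, homogeneous_symmetric_run):
        tree, _, result = homogeneous_symmetric_run
        assert nv.detect_pendelluft(result, tree, 0.02) == []

    def test_heterogeneous_compliance_produces_end_inspiratory_events(
        self, default_artifacts, default_result
    ):
        events = nv.detect_pendelluft(default_result, default_artifacts.tree, 0.02)
        assert events
        period, t_insp, _ = nv.inspiratory_times(default_artifacts.settings)
        phases = np.array([e.time % period for e in events])
        # at least one event in the last third of an inspiration phase
        assert np.any((phases > 2 * t_insp / 3) & (phases <= t_insp + 1e-9))

    def test_agrees_with_brute_force_sign_scan(self, default_artifacts, default_result):
        tree, r = default_artifacts.tree, default_result
        thr = 0.02 * np.max(np.abs(r.inlet_flow))
        idx = {sid: i for i, sid in enumerate(r.segment_ids)}
        count = 0
        for parent in tree.segments.values():
            kids = tree.children(parent.id)
            if len(kids) != 2:
                continue
            qa = r.segment_flows[idx[kids[0].id]]
            qb = r.segment_flows[idx[kids[1].id]]
            for k in range(len(r.times)):
                if qa[k] * qb[k] < 0 and abs(qa[k]) > thr and abs(qb[k]) > thr:
                    count += 1
        assert len(nv.detect_pendelluft(r, tree, 0.02)) == count

    def test_events_vanish_continuously_with_severity(self, symmetric_tree, default_patient):
        counts = []
        for sev in (0.6, 0.3, 0.0):
            w = nv.make_compliance_heterogeneity(128, "bpd_patchy", sev, seed=3)
            units = nv.build_terminal_units(
                symmetric_tree, default_patient.crs_total, w,
                diameter_ratio=0.79, length_ratio=0.79,
            )
            res = nv.simulate(
                symmetric_tree, units, nv.TubeModel(),
                nv.LeakModel(regime="linear", resistance=0.38),
                nv.HFOVSettings(n_cycles=3), default_patient.body_mass,
            )
            counts.append(len(nv.detect_pendelluft(res, symmetric_tree, 0.02)))
        assert counts[0] >= counts[1] >= counts[2] == 0
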