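"""Mechanics layer: SOT fitting, compliance partition, resistances, closure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neovent as nv
from neovent.mechanics import (
    AirProperties,
    equivalent_downstream_resistance,
    estimate_crs_sot,
    partition_compliance,
    poiseuille_resistance,
    terminal_pressure,
)


class TestSOTEstimation:
    def test_noise_free_recovery_of_compliance(self, default_patient):
        m = nv.make_sot_maneuver(default_patient, resistance=0.005, occlusion_volume=10.0)
        est = estimate_crs_sot(m)
        assert est.crs == pytest.approx(20.93, rel=1e-3)
        assert est.crs == pytest.approx(default_patient.crs_total, rel=1e-4)

    def test_estimator_inverts_generator_time_constant(self, default_patient):
        # R*C = 0.2 s by construction
        r = 0.2 / default_patient.crs_total
        m = nv.make_sot_maneuver(default_patient, r, occlusion_volume=8.0)
        est = estimate_crs_sot(m)
        assert est.time_constant == pytest.approx(0.2, rel=1e-4)
        assert est.resistance == pytest.approx(r, rel=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        r=st.floats(0.001, 0.05),
        c=st.floats(5.0, 50.0),
        v0=st.floats(2.0, 20.0),
    )
    def test_noise_free_identity_for_any_mechanics(self, r, c, v0):
        p = nv.make_patient({"crs_total": c})
        est = estimate_crs_sot(nv.make_sot_maneuver(p, r, v0))
        assert est.crs == pytest.approx(c, rel=1e-4)
        assert est.time_constant == pytest.approx(r * c, rel=1e-4)

    def test_noisy_recovery_is_unbiased_within_monte_carlo_spread(self, default_patient):
        truth = default_patient.crs_total
        estimates = [
            estimate_crs_sot(
                nv.make_sot_maneuver(
                    default_patient, 0.005, 10.0, noise_sd=4.0, seed=s
                )
            ).crs
            for s in range(100)
        ]
        estimates = np.asarray(estimates)
        assert abs(estimates.mean() - truth) < 2.0 * estimates.std()

    def test_rejects_nonpassive_trace(self, default_patient):
        m = nv.make_sot_maneuver(default_patient, 0.005, 10.0)
        bad = nv.SOTManeuver(
            time=m.time, flow=m.flow[::-1].copy(), volume=m.volume,
            plateau_pressure=m.plateau_pressure,
        )
        with pytest.raises(ValueError):
            estimate_crs_sot(bad)


class TestCompliancePartition:
    def test_uniform_split_over_128_terminals(self, default_tree, default_patient):
        w = nv.make_compliance_heterogeneity(128, "uniform")
        c_map = partition_compliance(default_patient.crs_total, default_tree, w)
        for c in c_map.values():
            assert c == pytest.approx(20.93 / 128, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(seed=st.integers(0, 10_000), severity=st.floats(0.0, 0.9))
    def test_parallel_sum_conserved_exactly(self, default_tree, default_patient, seed, severity):
        w = nv.make_compliance_heterogeneity(128, "bpd_patchy", severity, seed)
        c_map = partition_compliance(default_patient.crs_total, default_tree, w)
        assert sum(c_map.values()) == pytest.approx(default_patient.crs_total, abs=1e-10)

    def test_patch_terminals_have_reduced_compliance(self, default_tree, default_patient):
        w = nv.make_compliance_heterogeneity(128, "bpd_patchy", 0.5, seed=2)
        c_map = partition_compliance(default_patient.crs_total, default_tree, w)
        values = np.array(list(c_map.values()))
        assert values.min() / values.max() == pytest.approx(0.5, rel=1e-9)

    def test_weight_count_mismatch_rejected(self, default_tree):
        with pytest.raises(ValueError, match="weights"):
            partition_compliance(20.93, default_tree, np.full(64, 1 / 64))


class TestPoiseuille:
    def test_hand_evaluated_reference_value(self):
        # independent SI arithmetic: R = 128 mu L / (pi d^4)
        seg = nv.AirwaySegment("x", None, 0, length=40.0, diameter=4.0)
        mu = 1.27 * 17.0e-6                      # Pa s
        r_si = 128.0 * mu * 0.040 / (math.pi * 0.004**4)
        assert poiseuille_resistance(seg) == pytest.approx(r_si * 1e-9, rel=1e-12)

    def test_fourth_power_diameter_law(self):
        a = nv.AirwaySegment("a", None, 0, length=10.0, diameter=1.0)
        b = nv.AirwaySegment("b", None, 0, length=10.0, diameter=2.0)
        assert poiseuille_resistance(a) / poiseuille_resistance(b) == pytest.approx(16.0)

    def test_series_additivity(self):
        half = nv.AirwaySegment("h", None, 0, length=5.0, diameter=1.5)
        full = nv.AirwaySegment("f", None, 0, length=10.0, diameter=1.5)
        assert 2 * poiseuille_resistance(half) == pytest.approx(
            poiseuille_resistance(full), rel=1e-12
        )


def brute_force_downstream_resistance(d_t, l_t, extra, dr, lr, air):
    """Independent oracle: enumerate the virtual subtree as an explicit
    resistor network, ground the deepest ends, inject unit flow at the inlet
    and read the inlet pressure from the dense nodal system."""
    segments = []  # (node_from, node_to, resistance)
    nodes = {"inlet": 0}

    def build(path, g, parent_node):
        if g > extra:
            return
        seg = nv.AirwaySegment(
            f"v{path}", None, g, length=l_t * lr**g, diameter=d_t * dr**g
        )
        r = poiseuille_resistance(seg, air)
        node = nodes.setdefault(path, len(nodes))
        segments.append((parent_node, node, r))
        build(path + "L", g + 1, node)
        build(path + "R", g + 1, node)

    build("L", 1, 0)
    build("R", 1, 0)
    n = len(nodes)
    deepest = {
        nodes[p] for p in nodes if p != "inlet" and len(p) == extra
    }
    a = np.zeros((n, n))
    rhs = np.zeros(n)
    for u, v, r in segments:
        g = 1.0 / r
        a[u, u] += g
        a[v, v] += g
        a[u, v] -= g
        a[v, u] -= g
    rhs[0] = 1.0  # unit flow injection
    for d in deepest:  # grounded ends
        a[d, :] = 0.0
        a[d, d] = 1.0
        rhs[d] = 0.0
    p = np.linalg.solve(a, rhs)
    return p[0]


class TestDownstreamResistance:
    def test_one_extra_generation_is_parallel_halving(self):
        air = AirProperties()
        d_t, l_t = 0.6, 5.0
        child = nv.AirwaySegment("c", None, 1, length=l_t * 0.79, diameter=d_t * 0.79)
        expected = poiseuille_resistance(child, air) / 2.0
        got = equivalent_downstream_resistance(d_t, l_t, extra_generations=1)
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("extra", [1, 2, 3, 4])
    def test_matches_brute_force_network_reduction(self, extra):
        air = AirProperties()
        got = equivalent_downstream_resistance(
            0.61, 5.3, extra_generations=extra, diameter_ratio=0.79, length_ratio=0.79
        )
        brute = brute_force_downstream_resistance(0.61, 5.3, extra, 0.79, 0.79, air)
        assert got == pytest.approx(brute, rel=1e-10)

    def test_self_similar_limit_is_geometric_series(self):
        # ratios -> 1: R_eq -> sum_g R_seg / 2^g with constant R_seg
        d_t, l_t, extra = 0.6, 5.0, 9
        r1 = 1.0 - 1e-12
        seg = nv.AirwaySegment("s", None, 1, length=l_t, diameter=d_t)
        r_seg = poiseuille_resistance(seg)
        expected = r_seg * sum(0.5**g for g in range(1, extra + 1))
        got = equivalent_downstream_resistance(
            d_t, l_t, extra, diameter_ratio=r1, length_ratio=r1
        )
        assert got == pytest.approx(expected, rel=1e-6)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            equivalent_downstream_resistance(0.6, 5.0, 9, diameter_ratio=1.2)


class TestTerminalClosure:
    def test_rest_is_a_fixed_point(self):
        u = nv.TerminalUnit("t", r_eq=0.1, c_eq=1.0)
        u2 = terminal_pressure(u, q=0.0, dt=0.01)
        assert u2.pressure == 0.0
        assert u2.delta_v == 0.0

    def test_pure_capacitor_ramps_linearly(self):
        # r_eq = 0, constant q applied from t <= 0: P = q t / C
        q, c, dt, n = 5.0, 2.0, 1e-3, 500
        u = nv.TerminalUnit("t", r_eq=0.0, c_eq=c, flow=q)
        for _ in range(n):
            u = terminal_pressure(u, q, dt)
        assert u.pressure == pytest.approx(q * n * dt / c, rel=1e-12)

    def test_sinusoidal_flow_matches_symbolic_integral(self):
        # q = q0 sin(w t): dV = q0 (1 - cos(w t))/w, P = R q + dV/C
        q0, w, r, c = 10.0, 2 * math.pi * 10.0, 0.05, 0.2
        dt, n = 1e-5, 5000  # t = 0.05 s
        u = nv.TerminalUnit("t", r_eq=r, c_eq=c, flow=0.0)
        for k in range(1, n + 1):
            u = terminal_pressure(u, q0 * math.sin(w * k * dt), dt)
        t = n * dt
        dv = q0 * (1 - math.cos(w * t)) / w
        expected = r * q0 * math.sin(w * t) + dv / c
        assert u.pressure == pytest.approx(expected, rel=1e-4)

    def test_estimate_validates_time_constant_consistency(self):
        with pytest.raises(ValueError):
            nv.MechanicsEstimate(crs=20.0, resistance=0.01, time_constant=0.5,
                                 fit_diagnostics={})
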