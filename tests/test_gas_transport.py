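"""Oxygen transport: advection/diffusion oracles, conservation, metrics."""

import numpy as np
import pytest

import neovent as nv
from neovent.gas_transport import CFLError, TransportGrid, TransportParams, advance_transport


def single_segment(length=100.0, diameter=2.0):
    seg = nv.AirwaySegment("T", None, 0, length=length, diameter=diameter,
                           is_terminal=True)
    return nv.AirwayTree(segments={"T": seg}, root_id="T")


class TestAdvectionOracle:
    def test_front_advances_at_flow_velocity(self):
        """Pure advection (D = 0): the 0.35/0.21 front position equals u t
        to within one cell (method of characteristics)."""
        tree = single_segment(length=100.0, diameter=2.0)
        params = TransportParams(diffusivity=0.0, cells_per_segment=100,
                                 initial_concentration=0.21)
        grid = TransportGrid(tree, params)
        field = grid.new_field()
        area = tree.root.area_mm2
        u = 500.0                      # mm/s
        q_ml_s = u * area / 1000.0
        t_total, n_steps = 0.12, 240
        for _ in range(n_steps):
            field = advance_transport(field, np.array([q_ml_s]), tree, params,
                                      t_total / n_steps)
        phi = field.phi[0]
        mid = 0.5 * (0.35 + 0.21)
        front_cell = np.argmax(phi < mid)
        dx = 100.0 / 100
        assert abs(front_cell * dx - u * t_total) <= 2 * dx

    def test_equilibrium_field_is_fixed_point(self):
        tree = single_segment()
        params = TransportParams(initial_concentration=0.35)
        grid = TransportGrid(tree, params)
        field = grid.new_field()
        for _ in range(50):
            field = advance_transport(field, np.array([5.0]), tree, params, 1e-3)
        np.testing.assert_allclose(field.phi, 0.35, atol=1e-12)


class TestDiffusion:
    def test_no_flow_conserves_total_oxygen(self):
        tree = single_segment()
        params = TransportParams(cells_per_segment=50)
        grid = TransportGrid(tree, params)
        field = grid.new_field()
        field.phi[0, 20:30] = 0.9           # arbitrary bump, closed ends
        before = field.total_oxygen_ml()
        for _ in range(200):
            field = advance_transport(field, np.array([0.0]), tree, params, 1e-3)
        assert field.total_oxygen_ml() == pytest.approx(before, rel=1e-10)

    def test_variance_grows_at_2dt(self):
        """A narrow pulse spreads with variance growth 2 D t (Gaussian)."""
        tree = single_segment(length=400.0, diameter=2.0)
        params = TransportParams(cells_per_segment=400, initial_concentration=0.0)
        grid = TransportGrid(tree, params)
        field = grid.new_field()
        field.phi[0, 198:202] = 1.0
        x = (np.arange(400) + 0.5) * 1.0     # cell centres, dx = 1 mm

        def variance(phi):
            m = phi.sum()
            mu = (phi * x).sum() / m
            return ((x - mu) ** 2 * phi).sum() / m

        v0 = variance(field.phi[0])
        t_total, n = 0.5, 100
        for _ in range(n):
            field = advance_transport(field, np.array([0.0]), tree, params,
                                      t_total / n)
        d_mm2 = 0.219 * 100.0
        assert variance(field.phi[0]) - v0 == pytest.approx(
            2 * d_mm2 * t_total, rel=0.05
        )


class TestStabilityAndBounds:
    def test_cfl_violation_names_limiting_segment(self):
        tree = single_segment()
        params = TransportParams()
        grid = TransportGrid(tree, params)
        field = grid.new_field()
        with pytest.raises(CFLError, match="T"):
            advance_transport(field, np.array([500.0]), tree, params, 1.0,
                              subcycle=False)

    def test_discrete_maximum_principle_on_default_run(self, default_gas):
        assert default_gas.terminal_concentration.min() >= 0.21 - 1e-12
        assert default_gas.terminal_concentration.max() <= 0.35 + 1e-12
        assert default_gas.final_field.phi.min() >= 0.21 - 1e-12
        assert default_gas.final_field.phi.max() <= 0.35 + 1e-12


class TestDeliveryMetrics:
    def test_threshold_above_inlet_concentration_reaches_nothing(self, default_gas, default_artifacts):
        df = nv.oxygen_delivery_metrics(default_gas, default_artifacts.tree,
                                        threshold=0.5)
        assert (df["classification"] == "unreached").all()

    def test_direct_and_delayed_regions_coexist_on_heterogeneous_tree(
        self, default_gas, default_artifacts
    ):
        df = nv.oxygen_delivery_metrics(default_gas, default_artifacts.tree, 0.25)
        counts = df["classification"].value_counts()
        assert counts.get("direct", 0) >= 1
        assert counts.get("delayed", 0) >= 1
        # direct regions lie on shorter root-to-leaf paths on average
        mean_paths = df.groupby("classification")["path_length_mm"].mean()
        assert mean_paths["direct"] < mean_paths["delayed"]

    def test_arrival_times_match_brute_force_scan(self, default_gas, default_artifacts):
        df = nv.oxygen_delivery_metrics(default_gas, default_artifacts.tree, 0.25)
        conc, times = default_gas.terminal_concentration, default_gas.times
        for i, row in df.iterrows():
            j = default_gas.terminal_ids.index(row["terminal_id"])
            hits = [k for k in range(conc.shape[1]) if conc[j, k] > 0.25]
            if not hits:
                assert row["classification"] == "unreached"
            else:
                assert row["first_arrival_s"] == pytest.approx(times[hits[0]])


class TestBudget:
    def test_closed_system_has_zero_fluxes_and_residual(self):
        tree = single_segment()
        params = TransportParams(cells_per_segment=20)
        grid = TransportGrid(tree, params)
        field = grid.new_field()
        from neovent.gas_transport import _substep

        _, tal = _substep(grid, field.phi, np.array([0.0]), 1e-3)
        assert tal == {"inlet_influx": 0.0, "leak_efflux": 0.0, "outlet_efflux": 0.0}

    def test_default_run_budget_closes_per_cycle(self, default_gas):
        b = nv.oxygen_budget(default_gas)
        assert (b["residual_ml"].abs() < 0.01 * b["inlet_influx_ml"]).all()

    def test_influx_linear_in_inlet_concentration(self, default_result, default_artifacts):
        tree = default_artifacts.tree
        b1 = nv.simulate_transport(
            default_result, tree,
            TransportParams(inlet_concentration=0.35, initial_concentration=0.0),
            n_cycles=1,
        ).budgets
        b2 = nv.simulate_transport(
            default_result, tree,
            TransportParams(inlet_concentration=0.70, initial_concentration=0.0),
            n_cycles=1,
        ).budgets
        assert b2["inlet_influx_ml"][0] == pytest.approx(
            2 * b1["inlet_influx_ml"][0], rel=1e-9
        )


class TestGridConvergence:
    def test_arrival_times_stable_under_refinement(self, default_result, default_artifacts):
        tree = default_artifacts.tree
        arr = {}
        for cells in (20, 40):
            gas = nv.simulate_transport(
                default_result, tree, TransportParams(cells_per_segment=cells),
                n_cycles=2,
            )
            df = nv.oxygen_delivery_metrics(gas, tree, 0.25)
            arr[cells] = df.set_index("terminal_id")["first_arrival_s"]
        both = arr[20].notna() & arr[40].notna()
        # coarse-cell transit bound: one coarse cell at the mean terminal speed
        diffs = (arr[20][both] - arr[40][both]).abs()
        assert np.median(diffs) < 0.01
        assert (arr[20].isna() == arr[40].isna()).mean() > 0.9
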