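"""Unsteady 0D airflow network solver for the resolved tree.

The resolved conducting tree is treated as an electrical-analogue network:
nodes at the Y-piece, the tube/trachea junction and the distal end of every
segment; branches with laminar resistance (optional inertance) for the tube
and each airway; a lumped R-C terminal closure behind every outlet
(P^i = R_eq^i Q^i + dV^i/C_eq^i); and a leak branch from the Y-piece to
ambient.  During inspiration the ventilator injects the prescribed half-sine
source flow at the Y-piece; during expiration the Y-piece is held at PEEP
(a pressure boundary) and flow develops freely from the regional mechanics.

Time stepping advances the terminal capacitors by the trapezoidal
(Crank-Nicolson) rule — matching the trapezoidal volume integration of the
terminal closure — with a simultaneous sparse linear solve for all nodal
pressures each step; the first step after every phase switch falls back to
implicit Euler because the boundary-condition change makes branch flows
discontinuous there.  Both rules are A-stable on the stiff R-C network.
Pressures are stored relative to the PEEP baseline.  Sign convention:
distal-ward flow positive, leak flow positive out of the circuit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .airway_tree import AirwayTree
from .mechanics import AirProperties, TerminalUnit, poiseuille_resistance
from .ventilator import (
    HFOVSettings,
    LeakModel,
    TubeModel,
    flow_waveform,
    inspiratory_times,
)

__all__ = [
    "NetworkState",
    "SimulationResult",
    "PendelluftEvent",
    "HFOVNetwork",
    "assemble_and_step",
    "simulate",
    "detect_steady_state",
    "detect_pendelluft",
]


@dataclass
class NetworkState:
    """Instantaneous network state (dict-keyed, for the functional API)."""

    time: float
    segment_flows: dict[str, float]
    nodal_pressures: dict[str, float]
    terminal_units: dict[str, TerminalUnit]
    cumulative_inlet_volume: float = 0.0
    cumulative_leak_volume: float = 0.0


@dataclass(frozen=True)
class PendelluftEvent:
    """Opposite-signed flow in two sibling airways at one time sample."""

    time: float
    parent_id: str
    sibling_ids: tuple[str, str]
    flows: tuple[float, float]


@dataclass
class SimulationResult:
    """Recorded trajectories of one HFOV run.

    ``inlet_flow`` is the flow at the proximal end of the endotracheal tube
    (after the leak), the quantity a clinical flow monitor sees.  All
    per-segment and per-terminal trajectories share the ``times`` axis.
    """

    times: np.ndarray                 # (n+1,)
    inlet_flow: np.ndarray            # tube flow, ml/s
    source_flow: np.ndarray           # prescribed ventilator flow, ml/s
    leak_flow: np.ndarray             # ml/s, positive out of circuit
    lung_volume_above_frc: np.ndarray  # ml, sum of terminal delta_v
    terminal_volumes: np.ndarray      # (n_terminals, n+1) ml
    segment_flows: np.ndarray         # (n_segments, n+1) ml/s
    segment_ids: list[str]
    terminal_ids: list[str]
    cycle_bounds: np.ndarray          # indices of cycle starts, length n_cycles+1
    tidal_volume_abs: float           # ml
    dt_insp: float
    dt_exp: float
    cumulative_inlet_volume: np.ndarray
    cumulative_leak_volume: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_bounds) - 1

    def end_expiratory_volumes(self) -> np.ndarray:
        """Lung volume above FRC at the end of each cycle (ml)."""
        return self.lung_volume_above_frc[self.cycle_bounds[1:]]

    def cycle_slice(self, k: int) -> slice:
        """Index slice covering cycle k (1-based), endpoints inclusive."""
        if not 1 <= k <= self.n_cycles:
            raise IndexError(f"cycle {k} out of range 1..{self.n_cycles}")
        return slice(self.cycle_bounds[k - 1], self.cycle_bounds[k] + 1)

    def to_long_frame(self, stride: int = 1) -> pd.DataFrame:
        """Tidy long-format export (time, variable, id, value)."""
        idx = np.arange(0, len(self.times), stride)
        frames = [
            pd.DataFrame(
                {
                    "time": self.times[idx],
                    "variable": name,
                    "id": "",
                    "value": arr[idx],
                }
            )
            for name, arr in (
                ("inlet_flow", self.inlet_flow),
                ("source_flow", self.source_flow),
                ("leak_flow", self.leak_flow),
                ("lung_volume_above_frc", self.lung_volume_above_frc),
            )
        ]
        for i, sid in enumerate(self.segment_ids):
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.times[idx],
                        "variable": "segment_flow",
                        "id": sid,
                        "value": self.segment_flows[i, idx],
                    }
                )
            )
        for i, tid in enumerate(self.terminal_ids):
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.times[idx],
                        "variable": "terminal_volume",
                        "id": tid,
                        "value": self.terminal_volumes[i, idx],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


class HFOVNetwork:
    """Assembled network with prefactored per-phase linear operators."""

    def __init__(
        self,
        tree: AirwayTree,
        units: dict[str, TerminalUnit],
        tube: TubeModel,
        leak: LeakModel | None,
        settings: HFOVSettings,
        body_mass: float,
        air: AirProperties = AirProperties(),
        dt: float | None = None,
        inertance: bool = False,
        trachea_nonlinearity_factor: float = 1.0,
    ) -> None:
        self.tree = tree
        self.units = units
        self.tube = tube
        self.leak = leak
        self.settings = settings
        self.body_mass = body_mass
        self.air = air
        self.inertance = inertance

        period, t_insp, t_exp = inspiratory_times(settings)
        self.period, self.t_insp, self.t_exp = period, t_insp, t_exp
        if dt is None:
            dt = t_insp / 200.0
        if dt > t_insp / 50.0:
            warnings.warn(
                f"dt = {dt:.3e} s exceeds t_insp/50 = {t_insp / 50.0:.3e} s; "
                "phase resolution may be poor",
                stacklevel=2,
            )
        # snap step counts so steps land exactly on the phase boundary
        self.n_insp = max(1, round(t_insp / dt))
        self.dt_insp = t_insp / self.n_insp
        self.n_exp = max(1, round(t_exp / dt))
        self.dt_exp = t_exp / self.n_exp

        # --- topology ---------------------------------------------------
        self.segment_list = list(tree.segments.values())
        self.seg_index = {s.id: i for i, s in enumerate(self.segment_list)}
        n_seg = len(self.segment_list)
        # node 0 = Y-piece, node 1 = tube/trachea junction, node 2+i = distal
        # end of segment i
        self.n_nodes = 2 + n_seg
        self.parent_node = np.empty(n_seg, dtype=int)
        for i, s in enumerate(self.segment_list):
            self.parent_node[i] = 1 if s.parent_id is None else 2 + self.seg_index[s.parent_id]
        self.own_node = 2 + np.arange(n_seg)

        # branch resistances (kPa s/ml)
        r_seg = np.array(
            [poiseuille_resistance(s, air) for s in self.segment_list]
        )
        central = np.array([s.generation <= 1 for s in self.segment_list])
        r_seg[central] *= trachea_nonlinearity_factor
        self.r_seg = r_seg
        self.r_tube = tube.resistance(air)
        if inertance:
            # rho L / A per branch, kPa s^2/ml
            self.i_seg = np.array(
                [
                    air.density * (s.length * 1e-3) / (s.area_mm2 * 1e-6) * 1e-9
                    for s in self.segment_list
                ]
            )
            self.i_tube = (
                air.density
                * (tube.length * 1e-3)
                / (np.pi * (tube.inner_diameter * 1e-3 / 2) ** 2)
                * 1e-9
            )
        else:
            self.i_seg = np.zeros(n_seg)
            self.i_tube = 0.0

        self.terminal_ids = [s.id for s in tree.terminals()]
        if set(self.terminal_ids) != set(units):
            raise ValueError("terminal units do not match the tree's terminal outlets")
        self.term_seg_idx = np.array([self.seg_index[t] for t in self.terminal_ids])
        self.term_nodes = self.own_node[self.term_seg_idx]
        self.c_eq = np.array([units[t].c_eq for t in self.terminal_ids])
        self.r_eq = np.array([units[t].r_eq for t in self.terminal_ids])
        if np.all(self.c_eq <= 0):
            raise ValueError(
                "terminal closure is singular: no positive regional compliance"
            )
        self.peep = settings.peep_kpa
        self.vt_abs = settings.tidal_volume_abs(body_mass)
        self._factorized: dict = {}

    # -- matrix assembly -------------------------------------------------
    def _effective_conductances(self, dt: float, first_step: bool):
        g_seg = 1.0 / (self.r_seg + self.i_seg / dt)
        g_tube = 1.0 / (self.r_tube + self.i_tube / dt)
        # implicit Euler on the phase-switch step, trapezoidal otherwise
        cap = dt / self.c_eq if first_step else dt / (2.0 * self.c_eq)
        g_term = 1.0 / (self.r_eq + cap)
        return g_seg, g_tube, g_term

    def _build_matrix(self, phase: str, dt: float, g_leak: float, first_step: bool):
        g_seg, g_tube, g_term = self._effective_conductances(dt, first_step)
        n = self.n_nodes
        rows, cols, vals = [], [], []

        def add(a, b, g):
            rows.extend((a, a))
            cols.extend((a, b))
            vals.extend((g, -g))
            rows.extend((b, b))
            cols.extend((b, a))
            vals.extend((g, -g))

        add(0, 1, g_tube)
        for i in range(len(self.segment_list)):
            add(self.parent_node[i], self.own_node[i], g_seg[i])
        for j, node in enumerate(self.term_nodes):
            rows.append(node)
            cols.append(node)
            vals.append(g_term[j])
        if phase == "insp" and g_leak > 0:
            rows.append(0)
            cols.append(0)
            vals.append(g_leak)
        a = sp.csr_matrix(
            sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
        )
        if phase == "exp":
            # Dirichlet: Y-piece held at PEEP (relative pressure 0)
            a = a.tolil()
            a[0, :] = 0.0
            a[0, 0] = 1.0
            a = a.tocsr()
        return splu(a.tocsc()), (g_seg, g_tube, g_term)

    def _solver_for(self, phase: str, dt: float, g_leak: float, first_step: bool):
        key = (phase, dt, g_leak, first_step)
        if key not in self._factorized:
            self._factorized[key] = self._build_matrix(phase, dt, g_leak, first_step)
        return self._factorized[key]

    # -- stepping --------------------------------------------------------
    def _linear_leak_conductance(self) -> float:
        if self.leak is None:
            return 0.0
        if self.leak.regime == "linear":
            return 1.0 / self.leak.resistance
        raise NotImplementedError  # orifice handled by Picard iteration

    def step_arrays(
        self,
        t_new: float,
        dt: float,
        phase: str,
        delta_v: np.ndarray,
        q_seg_prev: np.ndarray,
        q_tube_prev: float,
        q_term_prev: np.ndarray | None = None,
        first_step: bool = True,
    ):
        """Advance one implicit step; returns (pressures, q_seg, q_tube,
        q_leak, q_source, q_term, delta_v_new)."""
        orifice = self.leak is not None and self.leak.regime == "orifice"
        g_leak = 0.0 if orifice else self._linear_leak_conductance()
        lu, (g_seg, g_tube, g_term) = self._solver_for(phase, dt, g_leak, first_step)
        # Thevenin source of each terminal branch
        if first_step or q_term_prev is None:
            e_term = delta_v / self.c_eq
        else:
            e_term = (delta_v + 0.5 * q_term_prev * dt) / self.c_eq
        q_src = (
            flow_waveform(self.settings, self.body_mass, t_new)
            if phase == "insp"
            else 0.0
        )

        def solve(g_leak_eff: float, lu_used, refactor: bool):
            rhs = np.zeros(self.n_nodes)
            np.add.at(rhs, self.term_nodes, g_term * e_term)
            if phase == "insp":
                rhs[0] += q_src - g_leak_eff * self.peep
            if self.inertance:
                # branch EMF from backward-differenced inertance
                e_tube = -(self.i_tube / dt) * q_tube_prev
                rhs[0] -= g_tube * e_tube
                rhs[1] += g_tube * e_tube
                e_seg = -(self.i_seg / dt) * q_seg_prev
                np.add.at(rhs, self.parent_node, -g_seg * e_seg)
                np.add.at(rhs, self.own_node, g_seg * e_seg)
            if refactor:
                lu_used, _ = self._build_matrix(phase, dt, g_leak_eff, first_step)
            return lu_used.solve(rhs)

        if orifice and phase == "insp":
            from .ventilator import leak_flow as _leak_flow

            p = solve(0.0, lu, refactor=False)
            for _ in range(30):
                p_open = p[0] + self.peep
                g_eff = (
                    abs(_leak_flow(self.leak, p_open, self.air)) / abs(p_open)
                    if abs(p_open) > 1e-12
                    else 0.0
                )
                p_new = solve(g_eff, None, refactor=True)
                if abs(p_new[0] - p[0]) < 1e-10:
                    p = p_new
                    break
                p = 0.5 * (p + p_new)
            g_leak = g_eff
        else:
            p = solve(g_leak, lu, refactor=False)

        if self.inertance:
            q_tube = g_tube * (p[0] - p[1] + (self.i_tube / dt) * q_tube_prev)
            q_seg = g_seg * (
                p[self.parent_node] - p[self.own_node] + (self.i_seg / dt) * q_seg_prev
            )
        else:
            q_tube = g_tube * (p[0] - p[1])
            q_seg = g_seg * (p[self.parent_node] - p[self.own_node])
        q_term = g_term * (p[self.term_nodes] - e_term)
        if first_step or q_term_prev is None:
            delta_v_new = delta_v + q_term * dt
        else:
            delta_v_new = delta_v + 0.5 * (q_term_prev + q_term) * dt
        if self.leak is None:
            q_leak = 0.0
        elif self.leak.regime == "linear":
            q_leak = (p[0] + self.peep) / self.leak.resistance
        else:
            from .ventilator import leak_flow as _leak_flow

            q_leak = _leak_flow(self.leak, p[0] + self.peep, self.air)
        return p, q_seg, q_tube, q_leak, q_src, q_term, delta_v_new

    # -- full run --------------------------------------------------------
    def run(self, n_cycles: int | None = None) -> SimulationResult:
        n_cycles = n_cycles or self.settings.n_cycles
        n_seg = len(self.segment_list)
        n_term = len(self.terminal_ids)
        steps_per_cycle = self.n_insp + self.n_exp
        n_steps = n_cycles * steps_per_cycle

        times = np.zeros(n_steps + 1)
        q_tube_rec = np.zeros(n_steps + 1)
        q_src_rec = np.zeros(n_steps + 1)
        q_leak_rec = np.zeros(n_steps + 1)
        lung_vol = np.zeros(n_steps + 1)
        term_vol = np.zeros((n_term, n_steps + 1))
        seg_flow = np.zeros((n_seg, n_steps + 1))
        cum_in = np.zeros(n_steps + 1)
        cum_leak = np.zeros(n_steps + 1)

        delta_v = np.zeros(n_term)
        q_seg_prev = np.zeros(n_seg)
        q_term_prev = np.zeros(n_term)
        q_tube_prev = 0.0
        q_leak_prev = 0.0
        k = 0
        t = 0.0
        # record initial leak (Y at PEEP before the first inflation)
        q_leak_rec[0] = (
            self.peep / self.leak.resistance
            if self.leak is not None and self.leak.regime == "linear"
            else 0.0
        )
        for _cycle in range(n_cycles):
            for phase, n_sub, dt in (
                ("insp", self.n_insp, self.dt_insp),
                ("exp", self.n_exp, self.dt_exp),
            ):
                for j in range(n_sub):
                    first = j == 0
                    t_new = t + dt
                    p, q_seg, q_tube, q_leak, q_src, q_term, delta_v = (
                        self.step_arrays(
                            t_new, dt, phase, delta_v, q_seg_prev,
                            q_tube_prev, q_term_prev, first_step=first,
                        )
                    )
                    k += 1
                    t = t_new
                    times[k] = t
                    q_tube_rec[k] = q_tube
                    q_src_rec[k] = q_src
                    q_leak_rec[k] = q_leak
                    term_vol[:, k] = delta_v
                    lung_vol[k] = delta_v.sum()
                    seg_flow[:, k] = q_seg
                    # quadrature matching the capacitor update keeps the
                    # volume closure exact to round-off
                    if first:
                        d_in = (q_tube + q_leak) * dt
                        d_leak = q_leak * dt
                    else:
                        d_in = 0.5 * ((q_tube + q_leak) + (q_tube_prev + q_leak_prev)) * dt
                        d_leak = 0.5 * (q_leak + q_leak_prev) * dt
                    cum_in[k] = cum_in[k - 1] + d_in
                    cum_leak[k] = cum_leak[k - 1] + d_leak
                    q_seg_prev = q_seg
                    q_term_prev = q_term
                    q_tube_prev = q_tube
                    q_leak_prev = q_leak

        return SimulationResult(
            times=times,
            inlet_flow=q_tube_rec,
            source_flow=q_src_rec,
            leak_flow=q_leak_rec,
            lung_volume_above_frc=lung_vol,
            terminal_volumes=term_vol,
            segment_flows=seg_flow,
            segment_ids=[s.id for s in self.segment_list],
            terminal_ids=list(self.terminal_ids),
            cycle_bounds=np.arange(0, n_steps + 1, steps_per_cycle),
            tidal_volume_abs=self.vt_abs,
            dt_insp=self.dt_insp,
            dt_exp=self.dt_exp,
            cumulative_inlet_volume=cum_in,
            cumulative_leak_volume=cum_leak,
        )


def assemble_and_step(
    state: NetworkState,
    tree: AirwayTree,
    units: dict[str, TerminalUnit],
    tube: TubeModel,
    leak: LeakModel | None,
    settings: HFOVSettings,
    body_mass: float,
    dt: float,
    air: AirProperties = AirProperties(),
) -> NetworkState:
    """Functional single-step API over :class:`HFOVNetwork`.

    The phase (inspiration/expiration boundary condition) is chosen from the
    step's end time reduced modulo the cycle period; callers should align
    ``dt`` with the phase boundaries, as :func:`simulate` does.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    # fold the state's stored delta_v into fresh units for the network
    live_units = {
        tid: replace(units[tid], delta_v=state.terminal_units[tid].delta_v)
        for tid in units
    }
    net = HFOVNetwork(tree, live_units, tube, leak, settings, body_mass, air, dt=dt)
    t_new = state.time + dt
    _, t_insp, _ = inspiratory_times(settings)
    tm = t_new % net.period
    phase = "insp" if (tm > 0 and tm <= t_insp + 1e-12) else "exp"
    delta_v = np.array([state.terminal_units[t_].delta_v for t_ in net.terminal_ids])
    q_seg_prev = np.array(
        [state.segment_flows.get(s.id, 0.0) for s in net.segment_list]
    )
    p, q_seg, q_tube, q_leak, _q_src, q_term, delta_v_new = net.step_arrays(
        t_new, dt, phase, delta_v, q_seg_prev, 0.0
    )
    pressures = {"Y": p[0], "trachea_inlet": p[1]}
    pressures.update(
        {s.id: p[net.own_node[i]] for i, s in enumerate(net.segment_list)}
    )
    new_units = {}
    for j, tid in enumerate(net.terminal_ids):
        new_units[tid] = replace(
            units[tid],
            delta_v=delta_v_new[j],
            flow=q_term[j],
            pressure=units[tid].r_eq * q_term[j] + delta_v_new[j] / units[tid].c_eq,
        )
    return NetworkState(
        time=t_new,
        segment_flows={s.id: q_seg[i] for i, s in enumerate(net.segment_list)},
        nodal_pressures=pressures,
        terminal_units=new_units,
        cumulative_inlet_volume=state.cumulative_inlet_volume + (q_tube + q_leak) * dt,
        cumulative_leak_volume=state.cumulative_leak_volume + q_leak * dt,
    )


def simulate(
    tree: AirwayTree,
    units: dict[str, TerminalUnit],
    tube: TubeModel,
    leak: LeakModel | None,
    settings: HFOVSettings,
    body_mass: float,
    air: AirProperties = AirProperties(),
    dt: float | None = None,
    inertance: bool = False,
    n_cycles: int | None = None,
    trachea_nonlinearity_factor: float = 1.0,
) -> SimulationResult:
    """Run ``n_cycles`` HFOV cycles at fixed step size; deterministic."""
    net = HFOVNetwork(
        tree,
        units,
        tube,
        leak,
        settings,
        body_mass,
        air,
        dt=dt,
        inertance=inertance,
        trachea_nonlinearity_factor=trachea_nonlinearity_factor,
    )
    return net.run(n_cycles=n_cycles)


def detect_steady_state(
    result: SimulationResult, tol_fraction_of_vt: float = 0.02
) -> int | None:
    """First cycle k (k >= 2) whose end-expiratory volume differs from the
    previous cycle's by less than ``tol_fraction_of_vt`` of the tidal volume;
    ``None`` if never reached."""
    if result.n_cycles < 2:
        raise ValueError("need at least 2 complete cycles")
    eev = result.end_expiratory_volumes()
    tol = tol_fraction_of_vt * result.tidal_volume_abs
    for k in range(2, result.n_cycles + 1):
        if abs(eev[k - 1] - eev[k - 2]) < tol:
            return k
    return None


def detect_pendelluft(
    result: SimulationResult,
    tree: AirwayTree,
    threshold_fraction: float = 0.02,
) -> list[PendelluftEvent]:
    """Find interregional (pendelluft) flow events.

    An event is a time sample where two sibling segments carry
    opposite-signed flows, both exceeding ``threshold_fraction`` of the peak
    recorded inlet flow in magnitude.  Regional time-constant differences
    (e.g. patchy BPD compliance) produce such events near end-inspiration;
    a perfectly symmetric, homogeneous lung cannot.
    """
    peak = float(np.max(np.abs(result.inlet_flow)))
    if peak == 0.0:
        return []
    thr = threshold_fraction * peak
    idx = {sid: i for i, sid in enumerate(result.segment_ids)}
    events: list[PendelluftEvent] = []
    for parent in tree.segments.values():
        kids = tree.children(parent.id)
        if len(kids) != 2:
            continue
        qa = result.segment_flows[idx[kids[0].id]]
        qb = result.segment_flows[idx[kids[1].id]]
        mask = (qa * qb < 0) & (np.abs(qa) > thr) & (np.abs(qb) > thr)
        for k in np.nonzero(mask)[0]:
            events.append(
                PendelluftEvent(
                    time=float(result.times[k]),
                    parent_id=parent.id,
                    sibling_ids=(kids[0].id, kids[1].id),
                    flows=(float(qa[k]), float(qb[k])),
                )
            )
    events.sort(key=lambda e: (e.time, e.parent_id))
    return events
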