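"""Shared fixtures: all inputs are generated, nothing is downloaded.

Heavy artefacts (the calibrated default model and its six-cycle run) are
session-scoped so the acceptance-style tests share one simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

import neovent as nv
from neovent.config import load_config
from neovent.pipeline import build_model


@pytest.fixture(scope="session")
def default_patient() -> nv.PatientFixture:
    return nv.make_patient()


@pytest.fixture(scope="session")
def default_tree() -> nv.AirwayTree:
    """The packaged default morphometric tree, dead-space calibrated."""
    return nv.generate_tree(nv.MorphometryParams(), body_mass=0.76,
                            target_deadspace_per_kg=2.2)


@pytest.fixture(scope="session")
def symmetric_tree() -> nv.AirwayTree:
    return nv.generate_tree(
        nv.MorphometryParams(asymmetry_factor=0.0, jitter_sd=0.0),
        body_mass=0.76,
        target_deadspace_per_kg=2.2,
    )


@pytest.fixture(scope="session")
def default_artifacts():
    """Default pipeline model with the leak calibrated to a 16% fraction."""
    return build_model(load_config(None))


@pytest.fixture(scope="session")
def default_result(default_artifacts):
    """Six clinical-default HFOV cycles of the calibrated default model."""
    a = default_artifacts
    return nv.simulate(
        a.tree, a.units, a.tube, a.leak, a.settings, a.patient.body_mass
    )


@pytest.fixture(scope="session")
def homogeneous_symmetric_run(symmetric_tree, default_patient):
    """Perfectly symmetric tree with uniform compliances (no leak needed for
    the symmetry argument, but the default calibrated leak value is used)."""
    weights = nv.make_compliance_heterogeneity(
        len(symmetric_tree.terminals()), "uniform"
    )
    units = nv.build_terminal_units(
        symmetric_tree, default_patient.crs_total, weights,
        diameter_ratio=0.79, length_ratio=0.79,
    )
    leak = nv.LeakModel(regime="linear", resistance=0.38)
    result = nv.simulate(
        symmetric_tree, units, nv.TubeModel(), leak, nv.HFOVSettings(),
        default_patient.body_mass,
    )
    return symmetric_tree, units, result


@pytest.fixture(scope="session")
def default_gas(default_result, default_artifacts):
    """Oxygen transport over the first three recorded cycles."""
    return nv.simulate_transport(
        default_result, default_artifacts.tree, nv.TransportParams(), n_cycles=3
    )


def single_compartment_model(
    r_eq: float = 0.05, c_eq: float = 20.93, tube: nv.TubeModel | None = None
):
    """A one-segment 'tree' closed by a single lumped unit (oracle problems)."""
    seg = nv.AirwaySegment(
        id="T", parent_id=None, generation=0, length=27.0, diameter=3.2,
        is_terminal=True,
    )
    tree = nv.AirwayTree(segments={"T": seg}, root_id="T")
    units = {"T": nv.TerminalUnit(outlet_id="T", r_eq=r_eq, c_eq=c_eq)}
    return tree, units, tube or nv.TubeModel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
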