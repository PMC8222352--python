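import numpy as np
import pytest

from mdenm import (
    ProtocolConfig,
    ToyReceptorSpec,
    compute_modes,
    make_gated_receptor,
    select_modes,
)
from mdenm.enm import hessian


@pytest.fixture(scope="session")
def toy_receptor():
    """Default toy gated receptor: (structure, selection, potential)."""
    return make_gated_receptor()


@pytest.fixture(scope="session")
def toy_modes(toy_receptor):
    structure, _, potential = toy_receptor
    return compute_modes(hessian(potential, structure), structure.masses)


@pytest.fixture(scope="session")
def toy_selected_modes(toy_modes):
    return select_modes(toy_modes, 300.0, 3)


@pytest.fixture(scope="session")
def small_receptor():
    """A smaller, cheaper receptor for tests that only need a valid system."""
    return make_gated_receptor(ToyReceptorSpec(n_core=60, radius=7.0))


def make_diatomic(k=1.0, m=12.0, r=3.0):
    """Two equal-mass atoms on the x axis joined by one spring."""
    from mdenm import AtomLabel, Structure, build_network

    labels = [AtomLabel(1, "ATM", "CA"), AtomLabel(2, "ATM", "CA")]
    coords = np.array([0.0, 0.0, 0.0, r, 0.0, 0.0])
    s = Structure(labels, coords, np.array([m, m]), ["C", "C"])
    pot = build_network(s, cutoff=2 * r, uniform_k=k)
    return s, pot


@pytest.fixture()
def diatomic():
    return make_diatomic()
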