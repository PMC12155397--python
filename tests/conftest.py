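import numpy as np
import pytest

from noemin.fixtures import FixtureSpec, build_fixture
from noemin.model import Atom, BondGraph, Ensemble, Model
from noemin.perception import prepare_system


@pytest.fixture
def water_graph():
    """O-H1, O-H2 with O at index 0."""
    g = BondGraph(3)
    g.add_bond(0, 1)
    g.add_bond(0, 2)
    return g


@pytest.fixture
def chain_graph():
    """A-B-C linear chain."""
    g = BondGraph(3)
    g.add_bond(0, 1)
    g.add_bond(1, 2)
    return g


def make_atoms(spec):
    """spec: list of (name, element, resname, resnum) tuples."""
    return [
        Atom(serial=i + 1, name=n, element=e, residue_name=rn, residue_number=ri)
        for i, (n, e, rn, ri) in enumerate(spec)
    ]


@pytest.fixture
def acetate_system():
    ensemble, _ = build_fixture(FixtureSpec("acetate"))
    return prepare_system(ensemble)


@pytest.fixture
def tripeptide():
    ensemble, upl = build_fixture(
        FixtureSpec("ala_tripeptide", distortion_amplitude=0.3, seed=7, n_models=3)
    )
    return ensemble, upl


@pytest.fixture
def tripeptide_system(tripeptide):
    ensemble, upl = tripeptide
    return prepare_system(ensemble), upl


def finite_difference_forces(energy_fn, positions, h=1e-5):
    """Central finite differences of a scalar energy function."""
    pos = np.array(positions, dtype=float)
    forces = np.zeros_like(pos)
    for a in range(pos.shape[0]):
        for d in range(3):
            p = pos.copy()
            p[a, d] += h
            ep = energy_fn(p)
            p[a, d] -= 2 * h
            em = energy_fn(p)
            forces[a, d] = -(ep - em) / (2 * h)
    return forces
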