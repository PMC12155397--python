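import numpy as np
import pytest

from noemin.fixtures import FixtureSpec, build_fixture
from noemin.model import Atom, Ensemble, Model
from noemin.perception import (
    ARGININE_CZN_LENGTH,
    CARBOXYLATE_CO_LENGTH,
    TypingError,
    apply_bond_overrides,
    assign_uff_types,
    fix_termini,
    perceive_bonds,
    prepare_system,
)
from noemin.templates import RESIDUE_BONDS, hydrogen_parent

from conftest import make_atoms


def diatomic_ensemble(el, distance):
    atoms = [
        Atom(serial=1, name=f"{el.upper()}1", element=el, residue_name="LIG",
             residue_number=1, is_hetero=True),
        Atom(serial=2, name=f"{el.upper()}2", element=el, residue_name="LIG",
             residue_number=2, is_hetero=True),
    ]
    return Ensemble([Model(atoms, np.array([[0, 0, 0], [distance, 0, 0.0]]))])


def test_two_hydrogens_bond_at_074():
    # r_cov(H) = 0.31 each, +0.4 tolerance -> cutoff 1.02 >= 0.74
    graph = perceive_bonds(diatomic_ensemble("H", 0.74))
    assert len(graph) == 1


def test_two_hydrogens_no_bond_at_2A():
    graph = perceive_bonds(diatomic_ensemble("H", 2.0))
    assert len(graph) == 0


def test_ala_template_bond_count():
    ens, _ = build_fixture(FixtureSpec("ala_tripeptide"))
    graph = perceive_bonds(ens)
    atoms = ens.atoms
    # oracle: count expected edges from the stored template for residue 2
    res2 = [i for i, a in enumerate(atoms) if a.residue_number == 2]
    names = {atoms[i].name for i in res2}
    expected_heavy = sum(
        1 for a, b, _, _ in RESIDUE_BONDS["ALA"] if a in names and b in names
    )
    expected_h = sum(
        1 for i in res2
        if atoms[i].is_hydrogen and hydrogen_parent(atoms[i].name, names) in names
    )
    internal = sum(
        1 for b in graph.bonds if b.i in res2 and b.j in res2
    )
    assert internal == expected_heavy + expected_h
    # plus the two peptide links into residue 2
    crossing = sum(1 for b in graph.bonds if (b.i in res2) != (b.j in res2))
    assert crossing == 2


def test_perception_order_independent():
    ens, _ = build_fixture(FixtureSpec("acetate"))
    graph = perceive_bonds(ens)
    perm = np.random.default_rng(0).permutation(len(ens.atoms))
    atoms = [ens.atoms[i] for i in perm]
    pos = ens.models[0].positions[perm]
    permuted = perceive_bonds(Ensemble([Model(atoms, pos)]))
    inv = {int(p): k for k, p in enumerate(perm)}
    original = {(min(b.i, b.j), max(b.i, b.j)) for b in graph.bonds}
    mapped = {
        (min(inv_pair), max(inv_pair))
        for b in permuted.bonds
        for inv_pair in [(perm[b.i], perm[b.j])]
    }
    assert original == mapped


def test_methane_typed_c3():
    atoms = [Atom(1, "C1", "C", "LIG", 1, is_hetero=True)] + [
        Atom(i + 2, f"H{i+1}", "H", "LIG", 1, is_hetero=True) for i in range(4)
    ]
    t = 1.09 / np.sqrt(3)
    pos = np.array([[0, 0, 0], [t, t, t], [-t, -t, t], [-t, t, -t], [t, -t, -t]])
    ens = Ensemble([Model(atoms, pos)])
    types = assign_uff_types(ens, perceive_bonds(ens))
    assert types[0] == "C_3"
    assert all(t == "H_" for t in types[1:])


def test_benzene_typed_cr():
    angles = np.arange(6) * np.pi / 3
    pos = np.concatenate([
        1.39 * np.stack([np.cos(angles), np.sin(angles), np.zeros(6)], axis=1),
        2.47 * np.stack([np.cos(angles), np.sin(angles), np.zeros(6)], axis=1),
    ])
    atoms = [Atom(i + 1, f"C{i+1}", "C", "LIG", 1, is_hetero=True) for i in range(6)]
    atoms += [Atom(i + 7, f"H{i+1}", "H", "LIG", 1, is_hetero=True) for i in range(6)]
    ens = Ensemble([Model(atoms, pos)])
    types = assign_uff_types(ens, perceive_bonds(ens))
    assert types[:6] == ["C_R"] * 6


def test_unknown_element_typing_error():
    atoms = [Atom(1, "U1", "U", "LIG", 1, is_hetero=True)]
    ens = Ensemble([Model(atoms, np.zeros((1, 3)))])
    from noemin.model import BondGraph

    with pytest.raises(TypingError):
        assign_uff_types(ens, BondGraph(1))


# ---------------------------------------------------------------------------
# terminus fixing
# ---------------------------------------------------------------------------

def test_nterm_gets_three_hydrogens(tripeptide_system):
    system, _ = tripeptide_system
    atoms = system.atoms
    n_idx = next(
        i for i, a in enumerate(atoms) if a.residue_number == 1 and a.name == "N"
    )
    h_names = sorted(
        atoms[i].name for i in system.bonds.neighbors(n_idx) if atoms[i].is_hydrogen
    )
    assert h_names == ["H1", "H2", "H3"]


def test_cterm_gets_oxt(tripeptide_system):
    system, _ = tripeptide_system
    atoms = system.atoms
    assert any(a.name == "OXT" and a.residue_number == 3 for a in atoms)
    c_idx = next(
        i for i, a in enumerate(atoms) if a.residue_number == 3 and a.name == "C"
    )
    o_nbrs = [i for i in system.bonds.neighbors(c_idx) if atoms[i].element == "O"]
    assert len(o_nbrs) == 2


def test_added_hydrogen_geometry(tripeptide_system):
    system, _ = tripeptide_system
    atoms = system.atoms
    pos = system.ensemble.models[0].positions
    n_idx = next(
        i for i, a in enumerate(atoms) if a.residue_number == 1 and a.name == "N"
    )
    for i in system.bonds.neighbors(n_idx):
        if atoms[i].name in ("H2", "H3"):
            assert np.linalg.norm(pos[i] - pos[n_idx]) == pytest.approx(1.01, abs=1e-6)


def test_fix_termini_idempotent(tripeptide_system):
    system, _ = tripeptide_system
    again = fix_termini(system)
    assert len(again.atoms) == len(system.atoms)
    np.testing.assert_array_equal(
        again.ensemble.models[0].positions, system.ensemble.models[0].positions
    )


def test_nonstandard_terminus_untouched():
    atoms = make_atoms([("C1", "C", "XYZ", 1), ("O1", "O", "XYZ", 1)])
    ens = Ensemble([Model(atoms, np.array([[0, 0, 0], [1.2, 0, 0.0]]))])
    system = prepare_system(ens)
    assert len(system.atoms) == 2


# ---------------------------------------------------------------------------
# overrides
# ---------------------------------------------------------------------------

def test_acetate_two_overrides(acetate_system):
    values = sorted(acetate_system.bond_overrides.values())
    assert values == [CARBOXYLATE_CO_LENGTH] * 2


def test_arginine_three_overrides():
    ens, _ = build_fixture(FixtureSpec("methylguanidinium"))
    system = prepare_system(ens)
    assert sorted(system.bond_overrides.values()) == [ARGININE_CZN_LENGTH] * 3
    atoms = system.atoms
    cz = next(i for i, a in enumerate(atoms) if a.name == "CZ")
    for (i, j) in system.bond_overrides:
        assert cz in (i, j)


def test_uncharged_peptide_no_overrides():
    # peptide without terminus fixing: no COO- and no arginine -> no overrides
    ens, _ = build_fixture(FixtureSpec("gly_dipeptide"))
    system = prepare_system(ens, fix_terminal_residues=False)
    assert system.bond_overrides == {}


def test_protonated_acid_not_overridden():
    # COOH: one O carries H, so the two-terminal-oxygens motif must not match
    ens, _ = build_fixture(FixtureSpec("acetate"))
    atoms = [Atom(**vars(a)) for a in ens.atoms]
    pos = ens.models[0].positions.copy()
    atoms.append(Atom(8, "HO", "H", "ACT", 1, is_hetero=True))
    o2 = pos[2]
    pos = np.vstack([pos, o2 + np.array([0.6, -0.78, 0.0])])
    system = prepare_system(Ensemble([Model(atoms, pos)]))
    assert system.bond_overrides == {}
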