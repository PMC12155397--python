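import math

import numpy as np
import pytest

from noemin.fixtures import FixtureSpec, build_fixture
from noemin.forcefield import (
    ParameterError,
    UffCalculator,
    UffConfig,
    bond_force_constant,
    energy_forces,
    equilibrium_bond_length,
    get_params,
    load_params,
)
from noemin.perception import prepare_system

from conftest import finite_difference_forces


def system_for(kind, amplitude=0.0, seed=0, **kw):
    ens, _ = build_fixture(FixtureSpec(kind, distortion_amplitude=amplitude, seed=seed, **kw))
    return prepare_system(ens, fix_terminal_residues=False)


# ---------------------------------------------------------------------------
# parameters and combination rules
# ---------------------------------------------------------------------------

def test_param_table_loads():
    table = load_params()
    for label in ("H_", "C_3", "C_R", "N_R", "O_2", "O_3", "S_3+2", "Fe6+2"):
        assert label in table
        assert table[label].r1 > 0 and table[label].d1 > 0


def test_unknown_type_raises():
    with pytest.raises(ParameterError):
        get_params("Xx_9")
    with pytest.raises(ParameterError):
        equilibrium_bond_length("C_3", "Xx_9")


def test_hh_bond_length_hand_evaluated():
    # hand evaluation: equal electronegativities -> no EN correction,
    # single bond -> no BO correction, so r = 2 * r1(H_) = 0.708
    assert equilibrium_bond_length("H_", "H_", 1.0) == pytest.approx(0.708, abs=1e-12)


def test_c3_c3_bond_length_hand_evaluated():
    assert equilibrium_bond_length("C_3", "C_3", 1.0) == pytest.approx(1.514, abs=1e-12)


def test_aromatic_bond_order_correction():
    # r_BO = -0.1332 * (r_i + r_j) * ln(1.5), hand evaluated for C_R
    expected = 1.458 - 0.1332 * 1.458 * math.log(1.5)
    assert equilibrium_bond_length("C_R", "C_R", 1.5) == pytest.approx(expected, abs=1e-12)


def test_override_returned_verbatim():
    assert equilibrium_bond_length("C_R", "O_2", 1.5, override=1.25) == 1.25
    assert equilibrium_bond_length("C_R", "N_R", 1.5, override=1.34) == 1.34


# independent oracle: RDKit's UFF implementation
rdkit = pytest.importorskip("rdkit")


def _rdkit_mol(smiles):
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=1)
    return mol


@pytest.mark.parametrize(
    "smiles,idx,types,order",
    [
        ("CC", (0, 1), ("C_3", "C_3"), 1.0),
        ("O", (0, 1), ("O_3", "H_"), 1.0),
        ("N", (0, 1), ("N_3", "H_"), 1.0),
        ("c1ccccc1", (0, 1), ("C_R", "C_R"), 1.5),
        ("C=O", (0, 1), ("C_2", "O_2"), 2.0),
        ("S", (0, 1), ("S_3+2", "H_"), 1.0),
    ],
)
def test_bond_params_match_rdkit(smiles, idx, types, order):
    from rdkit.Chem import rdForceFieldHelpers as ffh

    kb, r0 = ffh.GetUFFBondStretchParams(_rdkit_mol(smiles), *idx)
    mine_r0 = equilibrium_bond_length(types[0], types[1], order)
    assert mine_r0 == pytest.approx(r0, abs=1e-6)
    assert bond_force_constant(types[0], types[1], mine_r0) == pytest.approx(kb, rel=1e-6)


def test_vdw_params_match_rdkit():
    from rdkit.Chem import rdForceFieldHelpers as ffh

    mol = _rdkit_mol("CC")
    x, d = ffh.GetUFFVdWParams(mol, 0, 2)  # C vs H
    pc, ph = get_params("C_3"), get_params("H_")
    assert math.sqrt(pc.x1 * ph.x1) == pytest.approx(x, abs=1e-9)
    assert math.sqrt(pc.d1 * ph.d1) == pytest.approx(d, abs=1e-9)


def test_minimized_benzene_matches_rdkit_uff():
    """End-to-end oracle: both implementations share one minimum geometry."""
    from rdkit.Chem import AllChem

    from noemin.minimizer import FireConfig, minimize_model
    from noemin.model import Atom, Ensemble, Model

    mol = _rdkit_mol("c1ccccc1")
    AllChem.UFFOptimizeMolecule(mol, maxIters=5000)
    conf = mol.GetConformer()
    pos = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    atoms = [
        Atom(i + 1, f"{a.GetSymbol()}{i+1}", a.GetSymbol(), "LIG", 1, is_hetero=True)
        for i, a in enumerate(mol.GetAtoms())
    ]
    system = prepare_system(Ensemble([Model(atoms, pos)]), fix_terminal_residues=False)
    model, report = minimize_model(
        system, 0, fire_config=FireConfig(max_steps=20000, force_tol=0.01)
    )
    cc = [np.linalg.norm(model.positions[i] - model.positions[(i + 1) % 6]) for i in range(6)]
    rdkit_cc = [np.linalg.norm(pos[i] - pos[(i + 1) % 6]) for i in range(6)]
    assert np.mean(cc) == pytest.approx(np.mean(rdkit_cc), abs=2e-3)


# ---------------------------------------------------------------------------
# energies and forces
# ---------------------------------------------------------------------------

def test_diatomic_at_equilibrium_zero_bond_energy():
    r0 = equilibrium_bond_length("H_", "H_", 1.0)
    system = system_for("diatomic", separation=r0)
    report = energy_forces(system)
    assert report.e_bond == pytest.approx(0.0, abs=1e-12)
    assert np.abs(report.forces).max() == pytest.approx(0.0, abs=1e-9)


def test_neon_pair_vdw_minimum():
    p = get_params("Ne4+4")
    ens, _ = build_fixture(FixtureSpec("diatomic", elements=("Ne", "Ne"), separation=p.x1))
    system = prepare_system(ens, fix_terminal_residues=False)
    assert len(system.bonds) == 0  # 3.24 A apart: no bond perceived
    report = energy_forces(system)
    assert report.e_vdw == pytest.approx(-p.d1, rel=1e-12)
    assert np.abs(report.forces).max() == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("kind,seed", [
    ("acetate", 1), ("acetate", 2), ("methylguanidinium", 3),
    ("valine_residue", 4), ("gly_dipeptide", 5),
])
def test_forces_match_finite_differences(kind, seed):
    system = system_for(kind, amplitude=0.15, seed=seed)
    calc = UffCalculator(system)
    pos = system.ensemble.models[0].positions
    analytic = calc.evaluate(pos).forces
    fd = finite_difference_forces(lambda p: calc.evaluate(p).e_total, pos)
    denom = np.maximum(1.0, np.abs(fd))
    assert (np.abs(analytic - fd) / denom).max() < 1e-4


def test_net_force_zero():
    system = system_for("ala_tripeptide", amplitude=0.2, seed=11)
    report = energy_forces(system)
    assert np.abs(report.forces.sum(axis=0)).max() < 1e-8


def test_energy_invariant_under_rigid_motion():
    system = system_for("acetate", amplitude=0.1, seed=2)
    calc = UffCalculator(system)
    pos = system.ensemble.models[0].positions
    e0 = calc.evaluate(pos).e_total
    shifted = pos + np.array([3.0, -7.0, 11.0])
    theta = 0.7
    rot = np.array([
        [math.cos(theta), -math.sin(theta), 0.0],
        [math.sin(theta), math.cos(theta), 0.0],
        [0.0, 0.0, 1.0],
    ])
    assert calc.evaluate(shifted).e_total == pytest.approx(e0, abs=1e-8)
    assert calc.evaluate(pos @ rot.T).e_total == pytest.approx(e0, abs=1e-8)


def test_term_decomposition():
    system = system_for("methylguanidinium", amplitude=0.1, seed=9)
    pos = system.ensemble.models[0].positions
    full = UffCalculator(system).evaluate(pos)
    assert full.e_total == pytest.approx(
        full.e_bond + full.e_angle + full.e_torsion + full.e_inversion + full.e_vdw,
        abs=1e-12,
    )
    no_tors = UffCalculator(system, UffConfig(include_torsions=False)).evaluate(pos)
    assert full.e_total - no_tors.e_total == pytest.approx(full.e_torsion, abs=1e-9)
    no_inv = UffCalculator(system, UffConfig(include_inversion=False)).evaluate(pos)
    assert full.e_total - no_inv.e_total == pytest.approx(full.e_inversion, abs=1e-9)


def test_vdw_excludes_12_13_includes_14():
    system = system_for("ala_tripeptide")
    terms = UffCalculator(system).terms
    pairs = set(zip(terms.nb_i.tolist(), terms.nb_j.tolist()))
    g = system.bonds
    for i, j in pairs:
        assert g.topological_distance(i, j, cap=2) not in (1, 2)
    # at least one 1-4 pair interacts
    found_14 = any(
        g.topological_distance(i, j, cap=3) == 3 for i, j in list(pairs)[:200]
    )
    assert found_14
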