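import numpy as np
import pytest

from noemin.fixtures import FixtureSpec, build_fixture
from noemin.forcefield import UffConfig, equilibrium_bond_length
from noemin.minimizer import (
    FireConfig,
    MinimizerState,
    fire_step,
    minimize_ensemble,
    minimize_model,
    minimize_positions,
)
from noemin.model import Ensemble, Model
from noemin.perception import prepare_system
from noemin.restraints import load_upl


def quadratic_provider(center, k=10.0):
    def provider(pos):
        d = pos - center
        return 0.5 * k * float((d**2).sum()), -k * d

    return provider


def test_fireconfig_validation():
    with pytest.raises(ValueError):
        FireConfig(f_dec=1.5)
    with pytest.raises(ValueError):
        FireConfig(dt_init=1.0, dt_max=0.1)


def test_first_step_moves_downhill():
    provider = quadratic_provider(np.array([[1.0, 0.0, 0.0]]))
    state = MinimizerState(
        positions=np.zeros((1, 3)), velocities=np.zeros((1, 3)), dt=1e-3, alpha=0.1
    )
    new_state, _, _ = fire_step(state, provider, FireConfig())
    assert new_state.positions[0, 0] > 0.0


def test_uphill_zeroes_velocities():
    provider = quadratic_provider(np.array([[1.0, 0.0, 0.0]]))
    state = MinimizerState(
        positions=np.zeros((1, 3)),
        velocities=np.array([[-1.0, 0.0, 0.0]]),  # moving against the force
        dt=1e-3,
        alpha=0.05,
        steps_since_uphill=7,
    )
    cfg = FireConfig()
    new_state, _, forces = fire_step(state, provider, cfg)
    # after the P <= 0 reset, velocity restarts from zero: v = dt * F only
    np.testing.assert_allclose(new_state.velocities, new_state.dt * forces)
    assert new_state.steps_since_uphill == 0
    assert new_state.alpha == cfg.alpha_start
    assert new_state.dt == pytest.approx(state.dt * cfg.f_dec)


def test_zero_force_is_fixed_point():
    def provider(pos):
        return 0.0, np.zeros_like(pos)

    state = MinimizerState(
        positions=np.ones((2, 3)), velocities=np.zeros((2, 3)), dt=1e-3, alpha=0.1
    )
    new_state, _, _ = fire_step(state, provider, FireConfig())
    np.testing.assert_array_equal(new_state.positions, state.positions)


def test_quadratic_well_converges_to_analytic_minimum():
    rng = np.random.default_rng(42)
    center = rng.normal(size=(4, 3))
    provider = quadratic_provider(center, k=25.0)
    start = center + rng.normal(scale=2.0, size=center.shape)
    cfg = FireConfig(max_steps=20000, force_tol=1e-4, dt_init=1e-3, dt_max=5e-2)
    final, report = minimize_positions(start, provider, cfg)
    assert report.converged
    np.testing.assert_allclose(final, center, atol=1e-4)


def test_nonfinite_force_aborts():
    def provider(pos):
        f = np.zeros_like(pos)
        f[0, 0] = np.nan
        return 0.0, f

    from noemin.minimizer import MinimizationError

    state = MinimizerState(
        positions=np.zeros((1, 3)), velocities=np.zeros((1, 3)), dt=1e-3, alpha=0.1
    )
    with pytest.raises(MinimizationError):
        fire_step(state, provider, FireConfig())


# ---------------------------------------------------------------------------
# molecular minimization
# ---------------------------------------------------------------------------

def test_already_minimal_diatomic_stays_put():
    r0 = equilibrium_bond_length("H_", "H_", 1.0)
    ens, _ = build_fixture(FixtureSpec("diatomic", separation=r0))
    system = prepare_system(ens, fix_terminal_residues=False)
    model, report = minimize_model(system, 0)
    assert report.converged
    np.testing.assert_allclose(
        model.positions, ens.models[0].positions, atol=1e-3
    )


def test_stretched_diatomic_relaxes_to_equilibrium():
    r0 = equilibrium_bond_length("H_", "H_", 1.0)
    ens, _ = build_fixture(FixtureSpec("diatomic", separation=r0))
    system = prepare_system(ens, fix_terminal_residues=False)
    assert len(system.bonds) == 1
    # stretch the bond to 1.5x equilibrium without touching the topology
    system.ensemble.models[0].positions[1, 0] = 1.5 * r0
    model, report = minimize_model(system, 0)
    assert report.converged
    d = np.linalg.norm(model.positions[0] - model.positions[1])
    assert d == pytest.approx(r0, abs=1e-3)


def test_two_atom_restrained_case():
    spec = FixtureSpec("two_atom_restraint_case", upper_limit=2.5, initial_distance=8.0)
    ens, upl = build_fixture(spec)
    system = prepare_system(ens, fix_terminal_residues=False)
    rs = load_upl(upl, system.atoms)
    assert len(rs.restraints) == 1
    model, report = minimize_model(
        system, 0, restraint_set=rs, ff_config=UffConfig(include_vdw=False)
    )
    d = np.linalg.norm(model.positions[0] - model.positions[1])
    assert d <= 2.5 + 1e-3


def test_final_energy_not_above_initial():
    ens, _ = build_fixture(FixtureSpec("acetate", distortion_amplitude=0.1, seed=5))
    system = prepare_system(ens)
    _, report = minimize_model(system, 0)
    assert report.final_energy <= report.initial_energy


def test_ensemble_three_models_all_converge(tripeptide_system):
    system, upl = tripeptide_system
    rs = load_upl(upl, system.atoms)
    minimized, reports = minimize_ensemble(system, rs)
    assert len(reports) == 3
    assert all(r.converged for r in reports)
    assert minimized.n_models == 3


def test_identical_models_identical_output():
    ens, _ = build_fixture(FixtureSpec("acetate", distortion_amplitude=0.1, seed=1, n_models=1))
    atoms = ens.atoms
    pos = ens.models[0].positions
    twin = Ensemble([Model(atoms, pos.copy()), Model(list(atoms), pos.copy())])
    system = prepare_system(twin)
    minimized, reports = minimize_ensemble(system)
    np.testing.assert_array_equal(
        minimized.models[0].positions, minimized.models[1].positions
    )
    assert reports[0].iterations == reports[1].iterations


def test_corrupt_model_reported_others_succeed():
    ens, _ = build_fixture(FixtureSpec("acetate", distortion_amplitude=0.05, seed=2, n_models=3))
    # wreck model 1: absurd coordinate overflows the energy evaluation
    ens.models[1].positions[0] = [1e200, 0.0, 0.0]
    system = prepare_system(ens)
    minimized, reports = minimize_ensemble(system)
    assert len(reports) == 3
    errors = [r.error is not None for r in reports]
    assert errors[1] and not errors[0] and not errors[2]
    assert all(r.converged for i, r in enumerate(reports) if i != 1)


def test_converged_reports_satisfy_force_criterion(tripeptide_system):
    system, _ = tripeptide_system
    cfg = FireConfig()
    _, reports = minimize_ensemble(system, fire_config=cfg)
    for r in reports:
        if r.converged:
            assert r.max_force < cfg.force_tol
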