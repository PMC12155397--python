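"""FIRE (fast inertial relaxation engine) minimization.

Canonical FIRE with semi-implicit Euler integration and unit masses:
velocities are mixed toward the force direction with weight alpha; after
``n_min`` consecutive downhill steps (power P = F.v > 0) the time step
grows and alpha decays; any uphill step zeroes the velocities and resets
dt and alpha.  Minimization only needs the fixed point, so the "masses"
and time units are arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .forcefield import EnergyForceReport, UffCalculator, UffConfig
from .model import Ensemble, Model
from .perception import TypedSystem
from .restraint_force import RestraintForceConfig, total_restraint_term
from .restraints import RestraintSet

__all__ = [
    "FireConfig",
    "MinimizerState",
    "ConvergenceReport",
    "MinimizationError",
    "fire_step",
    "minimize_positions",
    "minimize_model",
    "minimize_ensemble",
]


class MinimizationError(RuntimeError):
    """Non-finite forces or divergence during minimization."""


@dataclass
class FireConfig:
    dt_init: float = 1e-3
    dt_max: float = 1e-2
    alpha_start: float = 0.1
    f_inc: float = 1.1
    f_dec: float = 0.5
    f_alpha: float = 0.99
    n_min: int = 5
    max_steps: int = 5000
    force_tol: float = 0.05  # kcal/mol/A, max per-atom force magnitude

    def __post_init__(self) -> None:
        if not (0.0 < self.f_dec < 1.0 < self.f_inc):
            raise ValueError("need 0 < f_dec < 1 < f_inc")
        if not 0.0 < self.alpha_start < 1.0:
            raise ValueError("alpha_start must be in (0, 1)")
        if self.dt_init > self.dt_max:
            raise ValueError("dt_init must not exceed dt_max")


@dataclass
class MinimizerState:
    positions: np.ndarray
    velocities: np.ndarray
    dt: float
    alpha: float
    steps_since_uphill: int = 0
    iteration: int = 0


@dataclass
class ConvergenceReport:
    converged: bool
    iterations: int
    initial_energy: float
    final_energy: float
    max_force: float
    initial_report: EnergyForceReport | None = None
    final_report: EnergyForceReport | None = None
    error: str | None = None


ForceProvider = Callable[[np.ndarray], tuple[float, np.ndarray]]


def fire_step(
    state: MinimizerState,
    force_provider: ForceProvider,
    config: FireConfig,
    precomputed: tuple[float, np.ndarray] | None = None,
) -> tuple[MinimizerState, float, np.ndarray]:
    """One FIRE update; returns the new state plus the (energy, forces)
    evaluated at the input positions."""
    energy, forces = (
        precomputed if precomputed is not None else force_provider(state.positions)
    )
    if not np.all(np.isfinite(forces)):
        bad = int(np.argmax(~np.isfinite(forces).all(axis=1)))
        raise MinimizationError(f"non-finite force on atom index {bad}")

    v = state.velocities
    power = float(np.vdot(forces, v))
    dt, alpha = state.dt, state.alpha
    steps = state.steps_since_uphill

    if power > 0.0:
        steps += 1
        if steps > config.n_min:
            dt = min(dt * config.f_inc, config.dt_max)
            alpha *= config.f_alpha
    else:
        steps = 0
        v = np.zeros_like(v)
        dt *= config.f_dec
        alpha = config.alpha_start

    f_norm = float(np.linalg.norm(forces))
    v_norm = float(np.linalg.norm(v))
    if f_norm > 0.0 and v_norm > 0.0:
        v = (1.0 - alpha) * v + alpha * v_norm * forces / f_norm

    v = v + dt * forces  # unit masses
    new_positions = state.positions + dt * v

    return (
        MinimizerState(
            positions=new_positions,
            velocities=v,
            dt=dt,
            alpha=alpha,
            steps_since_uphill=steps,
            iteration=state.iteration + 1,
        ),
        energy,
        forces,
    )


def minimize_positions(
    positions: np.ndarray,
    force_provider: ForceProvider,
    config: FireConfig | None = None,
) -> tuple[np.ndarray, ConvergenceReport]:
    """Run FIRE until max per-atom |F| < force_tol or max_steps."""
    config = config or FireConfig()
    state = MinimizerState(
        positions=np.array(positions, dtype=float),
        velocities=np.zeros_like(np.asarray(positions, dtype=float)),
        dt=config.dt_init,
        alpha=config.alpha_start,
    )
    e0, f0 = force_provider(state.positions)
    best_positions = state.positions.copy()
    best_energy = e0
    energy, forces = e0, f0
    converged = False
    for _ in range(config.max_steps):
        max_force = float(np.sqrt((forces**2).sum(axis=1).max())) if forces.size else 0.0
        if max_force < config.force_tol:
            converged = True
            break
        state, _, _ = fire_step(state, force_provider, config, precomputed=(energy, forces))
        energy, forces = force_provider(state.positions)
        if energy < best_energy:
            best_energy = energy
            best_positions = state.positions.copy()
    final_energy, final_forces = force_provider(best_positions)
    max_force = (
        float(np.sqrt((final_forces**2).sum(axis=1).max())) if final_forces.size else 0.0
    )
    if not converged:
        converged = max_force < config.force_tol
    report = ConvergenceReport(
        converged=converged,
        iterations=state.iteration,
        initial_energy=e0,
        final_energy=final_energy,
        max_force=max_force,
    )
    if final_energy > e0 + 10.0 * max(1.0, abs(e0)):
        report.error = "divergence: final energy far above initial"
        raise MinimizationError(report.error)
    return best_positions, report


def _combined_provider(
    calc: UffCalculator,
    restraint_set: RestraintSet | None,
    restraint_config: RestraintForceConfig | None,
) -> Callable[[np.ndarray], tuple[float, np.ndarray, EnergyForceReport]]:
    def provider(positions: np.ndarray):
        report = calc.evaluate(positions)
        if restraint_set is not None and restraint_set.restraints:
            e_r, f_r = total_restraint_term(positions, restraint_set, restraint_config)
            report.e_restraint = e_r
            report.forces = report.forces + f_r
        return report.e_total, report.forces, report

    return provider


def minimize_model(
    system: TypedSystem,
    model_index: int,
    restraint_set: RestraintSet | None = None,
    fire_config: FireConfig | None = None,
    ff_config: UffConfig | None = None,
    restraint_config: RestraintForceConfig | None = None,
    calculator: UffCalculator | None = None,
) -> tuple[Model, ConvergenceReport]:
    """Minimize one model in the combined UFF + restraint potential."""
    calc = calculator or UffCalculator(system, ff_config)
    full = _combined_provider(calc, restraint_set, restraint_config)

    def provider(positions: np.ndarray) -> tuple[float, np.ndarray]:
        e, f, _ = full(positions)
        return e, f

    model = system.ensemble.models[model_index]
    new_positions, report = minimize_positions(model.positions, provider, fire_config)
    _, _, report.initial_report = full(model.positions)
    _, _, report.final_report = full(new_positions)
    return Model(model.atoms, new_positions), report


def minimize_ensemble(
    system: TypedSystem,
    restraint_set: RestraintSet | None = None,
    fire_config: FireConfig | None = None,
    ff_config: UffConfig | None = None,
    restraint_config: RestraintForceConfig | None = None,
) -> tuple[Ensemble, list[ConvergenceReport]]:
    """Minimize every model independently with identical settings.

    A model that fails (corrupt coordinates, divergence) keeps its input
    coordinates and its report carries the error; remaining models still
    run.
    """
    calc = UffCalculator(system, ff_config)
    models: list[Model] = []
    reports: list[ConvergenceReport] = []
    for idx, model in enumerate(system.ensemble.models):
        try:
            new_model, report = minimize_model(
                system, idx, restraint_set, fire_config, ff_config,
                restraint_config, calculator=calc,
            )
        except (MinimizationError, FloatingPointError, ValueError) as exc:
            models.append(Model(model.atoms, model.positions.copy()))
            reports.append(
                ConvergenceReport(
                    converged=False, iterations=0,
                    initial_energy=float("nan"), final_energy=float("nan"),
                    max_force=float("nan"), error=str(exc),
                )
            )
            continue
        models.append(new_model)
        reports.append(report)
    return Ensemble(models), reports
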