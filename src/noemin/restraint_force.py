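"""Flat-bottom upper-distance restraint potential.

Let D be the separation of the two endpoints and v = max(0, D - upper) the
violation.  The force magnitude is K * min(v, plateau) directed to pull the
endpoints together: harmonic up to a 5 A violation, constant beyond.  The
energy is the exact integral of that force law.  Forces on pseudoatom
endpoints are distributed evenly over the parent hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .restraints import RestraintSet

__all__ = [
    "RestraintForceConfig",
    "restraint_force_energy",
    "distribute_to_parents",
    "total_restraint_term",
    "DEFAULT_FORCE_CONSTANT",
    "FORCE_PLATEAU",
]

DEFAULT_FORCE_CONSTANT = 198.6  # kcal/mol/A
FORCE_PLATEAU = 5.0             # A of violation beyond which force is constant


@dataclass
class RestraintForceConfig:
    k: float = DEFAULT_FORCE_CONSTANT
    user_scale: float = 1.0
    plateau: float = FORCE_PLATEAU

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("force constant must be positive")
        if self.plateau <= 0:
            raise ValueError("plateau must be positive")
        if self.user_scale < 0:
            raise ValueError("user scale must be non-negative")

    @property
    def effective_k(self) -> float:
        return self.k * self.user_scale


def restraint_force_energy(
    p1: np.ndarray,
    p2: np.ndarray,
    upper: float,
    config: RestraintForceConfig | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Energy and forces of one upper-distance restraint.

    Returns ``(E, F_on_p1, F_on_p2)`` with equal and opposite forces.  A
    satisfied restraint contributes zero; beyond a ``plateau`` violation the
    force magnitude saturates at ``K * plateau`` and the energy continues
    linearly.
    """
    if upper <= 0:
        raise ValueError("upper limit must be positive")
    config = config or RestraintForceConfig()
    k = config.effective_k
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    delta = p1 - p2
    dist = float(np.linalg.norm(delta))
    v = max(0.0, dist - upper)
    if v == 0.0 or dist == 0.0 or k == 0.0:
        zero = np.zeros(3)
        return 0.0, zero.copy(), zero.copy()
    plateau = config.plateau
    if v <= plateau:
        energy = 0.5 * k * v**2
        magnitude = k * v
    else:
        energy = 0.5 * k * plateau**2 + k * plateau * (v - plateau)
        magnitude = k * plateau
    n = delta / dist
    f1 = -magnitude * n  # pulls p1 toward p2
    return energy, f1, -f1


def distribute_to_parents(
    f_pseudo: np.ndarray, parents: list[int] | tuple[int, ...]
) -> dict[int, np.ndarray]:
    """Split a pseudoatom force evenly: each parent gets F / N."""
    if len(parents) == 0:
        raise ValueError("pseudoatom has no parent atoms")
    share = np.asarray(f_pseudo, dtype=float) / len(parents)
    return {idx: share.copy() for idx in parents}


def total_restraint_term(
    positions: np.ndarray,
    restraint_set: RestraintSet,
    config: RestraintForceConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Aggregate restraint energy and per-real-atom force array for one model.

    Pseudoatom endpoint positions are the mean of their parent hydrogen
    positions; the resulting endpoint force is pushed back to the parents
    via :func:`distribute_to_parents`.
    """
    config = config or RestraintForceConfig()
    positions = np.asarray(positions, dtype=float)
    forces = np.zeros_like(positions)
    energy = 0.0
    for restraint in restraint_set.restraints:
        p1 = restraint.endpoint_i.position(positions)
        p2 = restraint.endpoint_j.position(positions)
        e, f1, f2 = restraint_force_energy(p1, p2, restraint.r_corrected, config)
        energy += e
        if e == 0.0:
            continue
        for f_endpoint, endpoint in ((f1, restraint.endpoint_i), (f2, restraint.endpoint_j)):
            for idx, share in distribute_to_parents(
                f_endpoint, endpoint.atom_indices
            ).items():
                forces[idx] += share
    return energy, forces
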