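"""Core domain types: atoms, models, ensembles and the covalent bond graph.

Conventions used throughout the package:

* coordinates are in Angstrom,
* energies in kcal/mol,
* forces in kcal/mol/Angstrom.

Atom identity for restraint matching is ``(residue_number, atom_name)``;
chain identifiers are carried along but only used when the input dialect
provides them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Model",
    "Ensemble",
    "Bond",
    "BondGraph",
    "EnsembleConsistencyError",
    "InvalidAtomIndexError",
    "BEYOND_CAP",
]

#: Sentinel returned by :meth:`BondGraph.topological_distance` when the
#: shortest bond path exceeds the requested cap (or no path exists).
BEYOND_CAP = -1


class EnsembleConsistencyError(ValueError):
    """Models of one ensemble do not share an identical atom list."""


class InvalidAtomIndexError(IndexError):
    """An atom index does not refer to an atom of the system."""


@dataclass
class Atom:
    """One atom record; coordinates live in :class:`Model`, not here."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str = "A"
    is_hetero: bool = False

    def key(self) -> tuple[str, int, str]:
        """Identity triple ``(chain_id, residue_number, name)``."""
        return (self.chain_id, self.residue_number, self.name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Model:
    """One conformer: an ordered atom list plus a ``(n, 3)`` coordinate array."""

    atoms: list[Atom]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.positions) != len(self.atoms):
            raise ValueError(
                f"{len(self.atoms)} atoms but {len(self.positions)} positions"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in model")

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Ensemble:
    """A set of models sharing a single topology (atom list and order)."""

    models: list[Model]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble needs at least one model")
        ref = [a.key() for a in self.models[0].atoms]
        for m_idx, model in enumerate(self.models[1:], start=2):
            keys = [a.key() for a in model.atoms]
            if keys != ref:
                culprit = _first_mismatch(ref, keys)
                raise EnsembleConsistencyError(
                    f"model {m_idx} atom list differs from model 1 "
                    f"(first mismatch: {culprit})"
                )

    @property
    def atoms(self) -> list[Atom]:
        """Shared atom list (taken from the first model)."""
        return self.models[0].atoms

    @property
    def n_atoms(self) -> int:
        return len(self.models[0].atoms)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def __iter__(self) -> Iterator[Model]:
        return iter(self.models)


def _first_mismatch(ref: Sequence, other: Sequence) -> str:
    for i, (a, b) in enumerate(zip(ref, other)):
        if a != b:
            return f"position {i}: {a} vs {b}"
    return f"length {len(ref)} vs {len(other)}"


@dataclass(frozen=True)
class Bond:
    """Undirected bond between atom indices ``i < j``."""

    i: int
    j: int
    order: float = 1.0
    aromatic: bool = False

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError(f"self-bond on atom {self.i}")
        if self.order < 1.0:
            raise ValueError(f"bond order {self.order} < 1")


class BondGraph:
    """Covalent bonds stored once per unordered pair, with order/aromatic flags."""

    def __init__(self, n_atoms: int, bonds: Iterable[Bond] = ()) -> None:
        self.n_atoms = int(n_atoms)
        self._bonds: dict[tuple[int, int], Bond] = {}
        self._adj: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for b in bonds:
            self.add_bond(b.i, b.j, order=b.order, aromatic=b.aromatic)

    # -- construction -------------------------------------------------------

    def add_bond(self, i: int, j: int, order: float = 1.0, aromatic: bool = False) -> None:
        self._check_index(i)
        self._check_index(j)
        if i == j:
            raise ValueError(f"self-bond on atom {i}")
        key = (min(i, j), max(i, j))
        self._bonds[key] = Bond(key[0], key[1], order=float(order), aromatic=aromatic)
        self._adj[i].add(j)
        self._adj[j].add(i)

    def remove_bond(self, i: int, j: int) -> None:
        key = (min(i, j), max(i, j))
        if key in self._bonds:
            del self._bonds[key]
            self._adj[i].discard(j)
            self._adj[j].discard(i)

    # -- queries ------------------------------------------------------------

    @property
    def bonds(self) -> list[Bond]:
        return sorted(self._bonds.values(), key=lambda b: (b.i, b.j))

    def has_bond(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self._bonds

    def get_bond(self, i: int, j: int) -> Optional[Bond]:
        return self._bonds.get((min(i, j), max(i, j)))

    def neighbors(self, atom_index: int) -> list[int]:
        """Bonded partners of ``atom_index``, sorted ascending."""
        self._check_index(atom_index)
        return sorted(self._adj[atom_index])

    def degree(self, atom_index: int) -> int:
        self._check_index(atom_index)
        return len(self._adj[atom_index])

    def topological_distance(self, i: int, j: int, cap: int = 6) -> int:
        """Minimum number of bonds on any path i -> j.

        Returns :data:`BEYOND_CAP` when the shortest path is longer than
        ``cap`` bonds or no path exists.
        """
        self._check_index(i)
        self._check_index(j)
        if cap < 1:
            raise ValueError("cap must be >= 1")
        if i == j:
            return 0
        frontier = {i}
        seen = {i}
        for depth in range(1, cap + 1):
            nxt: set[int] = set()
            for a in frontier:
                nxt |= self._adj[a]
            nxt -= seen
            if j in nxt:
                return depth
            if not nxt:
                return BEYOND_CAP
            seen |= nxt
            frontier = nxt
        return BEYOND_CAP

    def __len__(self) -> int:
        return len(self._bonds)

    def _check_index(self, i: int) -> None:
        if not 0 <= i < self.n_atoms:
            raise InvalidAtomIndexError(
                f"atom index {i} out of range for {self.n_atoms} atoms"
            )
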