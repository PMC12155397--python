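"""Bond perception, UFF atom typing, terminus fixing and bond overrides.

Bonds are taken from residue templates wherever a residue is one of the 20
standard amino acids; everything else (ligands, cofactors, inter-residue
links such as disulfides) falls back to a covalent-radius distance
criterion: bonded iff ``0.4 < d <= r_cov(i) + r_cov(j) + 0.4`` Angstrom.

Two ad-hoc equilibrium-length overrides are applied after typing: 1.25 A
for the C-O bonds of deprotonated carboxylates and 1.34 A for the CZ-N
bonds of arginine guanidinium groups, both of which have partial
double-bond character that plain UFF types render poorly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .model import Atom, BondGraph, Ensemble, Model
from .templates import (
    AMIDE_BOND_ORDER,
    STANDARD_RESIDUES,
    hydrogen_parent,
    template_bonds,
)

__all__ = [
    "PerceptionError",
    "TypingError",
    "TypedSystem",
    "COVALENT_RADII",
    "perceive_bonds",
    "assign_uff_types",
    "fix_termini",
    "apply_bond_overrides",
    "prepare_system",
    "CARBOXYLATE_CO_LENGTH",
    "ARGININE_CZN_LENGTH",
]

CARBOXYLATE_CO_LENGTH = 1.25
ARGININE_CZN_LENGTH = 1.34

BOND_TOLERANCE = 0.4  # added to the covalent-radius sum
MIN_BOND_DISTANCE = 0.4
MAX_BONDS_PER_ATOM = 6

# Cordero et al. single-bond covalent radii (A), subset relevant here.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24,
    "Cu": 1.32, "Zn": 1.22, "Se": 1.20, "Br": 1.20, "I": 1.39,
}


class PerceptionError(ValueError):
    """Coordinates or topology too corrupt for bond perception."""


class TypingError(KeyError):
    """No UFF type could be assigned for an atom."""


@dataclass
class TypedSystem:
    """An ensemble plus perceived bonds, UFF types and length overrides."""

    ensemble: Ensemble
    bonds: BondGraph
    uff_types: list[str]
    bond_overrides: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def atoms(self) -> list[Atom]:
        return self.ensemble.atoms


def _covalent_radius(element: str) -> float:
    try:
        return COVALENT_RADII[element.capitalize()]
    except KeyError:
        raise PerceptionError(f"no covalent radius for element {element!r}") from None


# ---------------------------------------------------------------------------
# bond perception
# ---------------------------------------------------------------------------

def perceive_bonds(ensemble: Ensemble) -> BondGraph:
    """Build the covalent bond graph from templates plus geometry.

    Uses the first model's coordinates for all distance tests.  Raises
    :class:`PerceptionError` if any atom ends up with more than six bonds.
    """
    atoms = ensemble.atoms
    pos = ensemble.models[0].positions
    graph = BondGraph(len(atoms))

    # group atom indices by residue
    residues: dict[tuple[str, int], list[int]] = {}
    for idx, atom in enumerate(atoms):
        residues.setdefault((atom.chain_id, atom.residue_number), []).append(idx)

    templated: set[int] = set()

    for (chain, resnum), indices in residues.items():
        res_atoms = [atoms[i] for i in indices]
        res_name = res_atoms[0].residue_name
        tmpl = template_bonds(res_name)
        if tmpl is None or any(a.is_hetero for a in res_atoms):
            continue
        by_name = {a.name: i for a, i in zip(res_atoms, indices)}
        heavy_names = {a.name for a in res_atoms if not a.is_hydrogen}
        placed: set[int] = set()
        for name_a, name_b, order, aromatic in tmpl:
            ia, ib = by_name.get(name_a), by_name.get(name_b)
            if ia is not None and ib is not None:
                graph.add_bond(ia, ib, order=order, aromatic=aromatic)
                placed.update((ia, ib))
        for a, i in zip(res_atoms, indices):
            if a.is_hydrogen:
                parent = hydrogen_parent(a.name, heavy_names)
                if parent is not None and parent in by_name:
                    graph.add_bond(i, by_name[parent], order=1.0)
                    placed.update((i, by_name[parent]))
        templated.update(placed)

    # backbone links between consecutive residue numbers on a chain
    for (chain, resnum), indices in residues.items():
        nxt = residues.get((chain, resnum + 1))
        if nxt is None:
            continue
        c_idx = next(
            (i for i in indices if atoms[i].name == "C" and i in templated), None
        )
        n_idx = next(
            (i for i in nxt if atoms[i].name == "N" and i in templated), None
        )
        if c_idx is None or n_idx is None:
            continue
        if np.linalg.norm(pos[c_idx] - pos[n_idx]) < 2.5:
            graph.add_bond(c_idx, n_idx, order=AMIDE_BOND_ORDER)

    _geometric_pass(atoms, pos, graph, templated)
    _assign_heuristic_orders(atoms, pos, graph, templated)

    for i in range(len(atoms)):
        if graph.degree(i) > MAX_BONDS_PER_ATOM:
            raise PerceptionError(
                f"atom {atoms[i].name} {atoms[i].residue_name}"
                f"{atoms[i].residue_number} has {graph.degree(i)} bonds; "
                "coordinates look corrupt"
            )
    return graph


def _geometric_pass(
    atoms: list[Atom],
    pos: np.ndarray,
    graph: BondGraph,
    templated: set[int],
) -> None:
    """Distance-criterion bonds for atoms not covered by templates.

    Pairs where both partners were placed by a template are only considered
    when they are sulfur atoms of different residues (disulfide bridges),
    which templates cannot express.
    """
    if len(atoms) < 2:
        return
    radii = np.array([_covalent_radius(a.element) for a in atoms])
    cutoff = radii.max() * 2 + BOND_TOLERANCE
    tree = cKDTree(pos)
    # hydrogens bond at most once, to the nearest eligible heavy atom
    h_candidates: dict[int, tuple[float, int]] = {}
    for i, j in sorted(tree.query_pairs(cutoff)):
        if graph.has_bond(i, j):
            continue
        ai, aj = atoms[i], atoms[j]
        if i in templated and j in templated:
            same_res = (ai.chain_id, ai.residue_number) == (aj.chain_id, aj.residue_number)
            disulfide = ai.element == "S" and aj.element == "S" and not same_res
            if not disulfide:
                continue
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if not (MIN_BOND_DISTANCE < d <= radii[i] + radii[j] + BOND_TOLERANCE):
            continue
        if ai.is_hydrogen or aj.is_hydrogen:
            for h, partner in ((i, j), (j, i)):
                if atoms[h].is_hydrogen and graph.degree(h) == 0:
                    best = h_candidates.get(h)
                    if best is None or d < best[0]:
                        h_candidates[h] = (d, partner)
            continue
        graph.add_bond(i, j, order=1.0)
    for h, (_, partner) in sorted(h_candidates.items()):
        if graph.degree(h) == 0 and (
            not atoms[partner].is_hydrogen or graph.degree(partner) == 0
        ):
            graph.add_bond(h, partner, order=1.0)


def _assign_heuristic_orders(
    atoms: list[Atom],
    pos: np.ndarray,
    graph: BondGraph,
    templated: set[int],
) -> None:
    """Valence/geometry bond-order heuristics for non-template atoms."""
    free = [i for i in range(len(atoms)) if i not in templated]
    free_set = set(free)
    # carbonyl / carboxylate / guanidinium motifs around carbon
    for c in free:
        if atoms[c].element != "C":
            continue
        nbrs = graph.neighbors(c)
        term_o = [
            n for n in nbrs
            if atoms[n].element == "O" and graph.degree(n) == 1
        ]
        n_nbrs = [n for n in nbrs if atoms[n].element == "N"]
        if len(term_o) >= 2:
            for o in term_o:
                graph.add_bond(c, o, order=1.5)
        elif len(term_o) == 1 and np.linalg.norm(pos[c] - pos[term_o[0]]) < 1.30:
            graph.add_bond(c, term_o[0], order=2.0)
        if len(nbrs) == 3 and len(n_nbrs) == 3:  # guanidinium-like
            for n in n_nbrs:
                graph.add_bond(c, n, order=1.5)
    # planar 5/6-rings of C/N/O/S among free atoms -> aromatic
    if free_set:
        g = nx.Graph()
        g.add_nodes_from(free)
        for b in graph.bonds:
            if b.i in free_set and b.j in free_set:
                g.add_edge(b.i, b.j)
        for ring in nx.cycle_basis(g):
            if len(ring) not in (5, 6):
                continue
            if any(atoms[i].element not in ("C", "N", "O", "S") for i in ring):
                continue
            if any(graph.degree(i) > 3 for i in ring):
                continue
            ring_pos = pos[ring]
            centered = ring_pos - ring_pos.mean(axis=0)
            # planarity: smallest singular value ~ rms out-of-plane deviation
            dev = np.linalg.svd(centered, compute_uv=False)[-1] / math.sqrt(len(ring))
            if dev > 0.15:
                continue
            for a, b_ in zip(ring, ring[1:] + ring[:1]):
                if graph.has_bond(a, b_):
                    graph.add_bond(a, b_, order=1.5, aromatic=True)


# ---------------------------------------------------------------------------
# UFF typing
# ---------------------------------------------------------------------------

# generic fallback UFF labels for elements without dedicated typing rules
_GENERIC_TYPES: dict[str, str] = {
    "He": "He4+4", "Li": "Li", "Be": "Be3+2", "B": "B_3", "F": "F_",
    "Ne": "Ne4+4", "Na": "Na", "Mg": "Mg3+2", "Al": "Al3", "Si": "Si3",
    "Cl": "Cl", "Ar": "Ar4+4", "K": "K_", "Ca": "Ca6+2", "Mn": "Mn6+2",
    "Fe": "Fe6+2", "Co": "Co6+3", "Ni": "Ni4+2", "Cu": "Cu3+1",
    "Zn": "Zn3+2", "Se": "Se3+2", "Br": "Br", "I": "I_",
}


def assign_uff_types(ensemble: Ensemble, bonds: BondGraph) -> list[str]:
    """Map every atom to a UFF type label from element plus connectivity."""
    atoms = ensemble.atoms
    types: list[str] = []
    for i, atom in enumerate(atoms):
        el = atom.element.capitalize()
        nbrs = bonds.neighbors(i)
        orders = [bonds.get_bond(i, n).order for n in nbrs]
        aromatic = any(bonds.get_bond(i, n).aromatic for n in nbrs)
        resonant = aromatic or any(o == 1.5 for o in orders)
        amide = any(abs(o - AMIDE_BOND_ORDER) < 1e-9 for o in orders)
        max_order = max(orders, default=1.0)
        deg = len(nbrs)

        if el == "H":
            types.append("H_")
        elif el == "C":
            if resonant:
                types.append("C_R")
            elif max_order >= 3.0 or (max_order >= 2.0 and deg <= 2):
                types.append("C_1")
            elif max_order >= 2.0 or amide:
                types.append("C_2")
            else:
                types.append("C_3")
        elif el == "N":
            if resonant or amide:
                types.append("N_R")
            elif max_order >= 3.0 or (max_order >= 2.0 and deg == 1):
                types.append("N_1")
            elif max_order >= 2.0:
                types.append("N_2")
            else:
                types.append("N_3")
        elif el == "O":
            if aromatic:
                types.append("O_R")
            elif max_order >= 1.5:
                types.append("O_2")
            else:
                types.append("O_3")
        elif el == "S":
            types.append("S_2" if max_order >= 2.0 else "S_3+2")
        elif el == "P":
            types.append("P_3+3")
        elif el in _GENERIC_TYPES:
            types.append(_GENERIC_TYPES[el])
        else:
            raise TypingError(
                f"no UFF type for element {el!r} "
                f"(atom {atom.name} {atom.residue_name}{atom.residue_number})"
            )
    return types


# ---------------------------------------------------------------------------
# terminus fixing
# ---------------------------------------------------------------------------

_N_H_LENGTH = 1.01
_TETRAHEDRAL = math.radians(109.47)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _orthonormal_frame(axis: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``axis``; u points along ref's component."""
    a = _unit(axis)
    r = ref - np.dot(ref, a) * a
    if np.linalg.norm(r) < 1e-8:
        r = np.array([1.0, 0.0, 0.0]) - a[0] * a
        if np.linalg.norm(r) < 1e-8:
            r = np.array([0.0, 1.0, 0.0]) - a[1] * a
    u = _unit(r)
    v = np.cross(a, u)
    return u, v


def fix_termini(system: TypedSystem) -> TypedSystem:
    """Complete standard-residue chain termini: N-terminal H1-H3, C-terminal OXT.

    Idempotent; chains whose terminal residue is not one of the 20 standard
    amino acids are left untouched.  Added atoms are appended to the atom
    list with the next free serial numbers, and the bond graph, types and
    overrides are updated (the completed carboxylate becomes resonant).
    """
    atoms = [Atom(**vars(a)) for a in system.atoms]
    positions = [m.positions.copy() for m in system.ensemble.models]
    graph = BondGraph(len(atoms), system.bonds.bonds)
    types = list(system.uff_types)

    chains: dict[str, list[int]] = {}
    for idx, atom in enumerate(atoms):
        if not atom.is_hetero and atom.residue_name in STANDARD_RESIDUES:
            chains.setdefault(atom.chain_id, []).append(idx)

    new_atoms: list[tuple[Atom, list[np.ndarray], int, str]] = []
    next_serial = max((a.serial for a in atoms), default=0) + 1

    def residue_indices(chain_idx: list[int], resnum: int) -> list[int]:
        return [i for i in chain_idx if atoms[i].residue_number == resnum]

    for chain_id, chain_idx in chains.items():
        resnums = sorted({atoms[i].residue_number for i in chain_idx})
        if not resnums:
            continue

        # ---- N terminus -------------------------------------------------
        first = residue_indices(chain_idx, resnums[0])
        by_name = {atoms[i].name: i for i in first}
        n_idx, ca_idx = by_name.get("N"), by_name.get("CA")
        if n_idx is not None and ca_idx is not None:
            res_name = atoms[n_idx].residue_name
            target_h = 2 if res_name == "PRO" else 3
            bound_h = [n for n in graph.neighbors(n_idx) if atoms[n].is_hydrogen]
            if len(bound_h) < target_h:
                for k, h in enumerate(sorted(bound_h), start=1):
                    atoms[h].name = f"H{k}"
                existing = len(bound_h)
                heavy_nbrs = [
                    n for n in graph.neighbors(n_idx) if not atoms[n].is_hydrogen
                ]
                for k in range(existing + 1, target_h + 1):
                    per_model = [
                        _amine_h_position(
                            pos[n_idx], pos[ca_idx],
                            [pos[h] for h in heavy_nbrs if h != ca_idx],
                            _ca_reference(pos, graph, atoms, ca_idx, n_idx),
                            slot=k - 1, n_slots=target_h,
                        )
                        for pos in positions
                    ]
                    atom = Atom(
                        serial=next_serial, name=f"H{k}", element="H",
                        residue_name=res_name,
                        residue_number=atoms[n_idx].residue_number,
                        chain_id=chain_id,
                    )
                    next_serial += 1
                    new_atoms.append((atom, per_model, n_idx, "H_"))

        # ---- C terminus -------------------------------------------------
        last = residue_indices(chain_idx, resnums[-1])
        by_name = {atoms[i].name: i for i in last}
        c_idx, ca_idx, o_idx = by_name.get("C"), by_name.get("CA"), by_name.get("O")
        if c_idx is not None and ca_idx is not None and o_idx is not None:
            o_nbrs = [n for n in graph.neighbors(c_idx) if atoms[n].element == "O"]
            if len(o_nbrs) == 1 and "OXT" not in by_name:
                per_model = []
                for pos in positions:
                    d = _unit(pos[c_idx] - pos[ca_idx])
                    o = _unit(pos[o_idx] - pos[c_idx])
                    mirrored = 2.0 * np.dot(o, d) * d - o  # reflect O across CA->C axis
                    per_model.append(pos[c_idx] + CARBOXYLATE_CO_LENGTH * _unit(mirrored))
                atom = Atom(
                    serial=next_serial, name="OXT", element="O",
                    residue_name=atoms[c_idx].residue_name,
                    residue_number=atoms[c_idx].residue_number,
                    chain_id=chain_id,
                )
                next_serial += 1
                new_atoms.append((atom, per_model, c_idx, "O_2"))
                # completed carboxylate becomes resonant
                graph.add_bond(c_idx, o_idx, order=1.5)
                types[o_idx] = "O_2"
                types[c_idx] = "C_R"

    if not new_atoms:
        return TypedSystem(system.ensemble, graph, types, dict(system.bond_overrides))

    n_old = len(atoms)
    grown = BondGraph(n_old + len(new_atoms), graph.bonds)
    for offset, (atom, per_model, partner, uff_type) in enumerate(new_atoms):
        idx = n_old + offset
        atoms.append(atom)
        types.append(uff_type)
        order = 1.5 if atom.name == "OXT" else 1.0
        grown.add_bond(idx, partner, order=order)
        for m, p in enumerate(per_model):
            positions[m] = np.vstack([positions[m], p])

    ensemble = Ensemble([Model(atoms, p) for p in positions])
    return TypedSystem(ensemble, grown, types, dict(system.bond_overrides))


def _ca_reference(pos, graph, atoms, ca_idx: int, n_idx: int) -> np.ndarray:
    """A substituent of CA other than N, used to stagger added amine protons."""
    for nbr in graph.neighbors(ca_idx):
        if nbr != n_idx and not atoms[nbr].is_hydrogen:
            return pos[nbr]
    for nbr in graph.neighbors(ca_idx):
        if nbr != n_idx:
            return pos[nbr]
    return pos[ca_idx] + np.array([1.0, 0.0, 0.0])


def _amine_h_position(
    n_pos: np.ndarray,
    ca_pos: np.ndarray,
    other_heavy: list[np.ndarray],
    ca_ref: np.ndarray,
    slot: int,
    n_slots: int,
) -> np.ndarray:
    """Ideal tetrahedral H position on an amine nitrogen.

    Primary amines (no heavy neighbor besides CA): three slots staggered
    about the N-CA bond relative to a CA substituent.  Secondary amines
    (proline): two slots straddling the C(D)-N-CA plane.
    """
    axis = _unit(n_pos - ca_pos)
    if not other_heavy:
        u, v = _orthonormal_frame(axis, ca_ref - ca_pos)
        phi = math.pi / 3.0 + slot * 2.0 * math.pi / 3.0  # staggered: 60, 180, 300
        tilt = math.pi - _TETRAHEDRAL  # angle from N->CA direction
        direction = (
            math.cos(tilt) * axis
            + math.sin(tilt) * (math.cos(phi) * u + math.sin(phi) * v)
        )
        return n_pos + _N_H_LENGTH * _unit(direction)
    # secondary amine: bisector of the two heavy bonds, tilted out of plane
    u1 = _unit(ca_pos - n_pos)
    u2 = _unit(other_heavy[0] - n_pos)
    bisector = -_unit(u1 + u2)
    out_of_plane = _unit(np.cross(u1, u2))
    half = _TETRAHEDRAL / 2.0
    sign = 1.0 if slot % 2 == 0 else -1.0
    direction = math.cos(half) * bisector + sign * math.sin(half) * out_of_plane
    return n_pos + _N_H_LENGTH * _unit(direction)


# ---------------------------------------------------------------------------
# bond-length overrides
# ---------------------------------------------------------------------------

def apply_bond_overrides(system: TypedSystem) -> TypedSystem:
    """Attach the two published equilibrium-length overrides.

    * every C-O bond of a deprotonated carboxylate (carbon with exactly two
      terminal oxygens) -> 1.25 A;
    * every CZ-N bond in an arginine residue -> 1.34 A.
    """
    atoms = system.atoms
    graph = system.bonds
    overrides = dict(system.bond_overrides)

    for i, atom in enumerate(atoms):
        if atom.element == "C":
            term_o = [
                n for n in graph.neighbors(i)
                if atoms[n].element == "O" and graph.degree(n) == 1
            ]
            if len(term_o) == 2:
                for o in term_o:
                    overrides[(min(i, o), max(i, o))] = CARBOXYLATE_CO_LENGTH
        if atom.name == "CZ" and atom.residue_name == "ARG":
            for n in graph.neighbors(i):
                if atoms[n].element == "N":
                    overrides[(min(i, n), max(i, n))] = ARGININE_CZN_LENGTH

    return TypedSystem(system.ensemble, graph, system.uff_types, overrides)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def prepare_system(ensemble: Ensemble, fix_terminal_residues: bool = True) -> TypedSystem:
    """Full perception pipeline: bonds, types, termini, overrides."""
    bonds = perceive_bonds(ensemble)
    types = assign_uff_types(ensemble, bonds)
    system = TypedSystem(ensemble, bonds, types)
    if fix_terminal_residues:
        system = fix_termini(system)
    return apply_bond_overrides(system)
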