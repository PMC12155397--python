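"""CYANA .upl upper-distance restraints: parsing, pseudoatoms, resolution.

An .upl line is whitespace-separated
``resnum_i resname_i atom_i resnum_j resname_j atom_j upper[A] ...``;
trailing fields and ``#`` comments are ignored.  Restraint endpoints are
matched by ``(residue_number, atom_name)``, first against real atoms and
then against pseudoatoms built from hydrogen naming rules:

* ``Q``   from H1, H2, H3
* ``QX``  from HX1, HX2, HX3
* ``QQX`` from HX11, HX12, HX13, HX21, HX22, HX23

where any subset of parents may be present.  Upper limits touching a
pseudoatom are widened by the r^-6 degeneracy factor
``r = r_p * (N_i * N_j)^(1/6)``.  Entries that cannot be identified are
kept in the ``unresolved`` list and end up in restraints.log.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .model import Atom

__all__ = [
    "Pseudoatom",
    "Endpoint",
    "RawEntry",
    "DistanceRestraint",
    "RestraintSet",
    "build_pseudoatoms",
    "parse_upl",
    "correct_pseudoatom_distance",
    "resolve",
    "load_upl",
    "format_restraints_log",
]


@dataclass
class Pseudoatom:
    """Virtual atom at the mean position of degenerate protons."""

    name: str
    residue_number: int
    parent_hydrogen_indices: list[int]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if not self.parent_hydrogen_indices:
            raise ValueError(f"pseudoatom {self.name} has no parents")

    @property
    def n_parents(self) -> int:
        return len(self.parent_hydrogen_indices)


@dataclass(frozen=True)
class Endpoint:
    """A resolved restraint endpoint: one atom or one pseudoatom."""

    atom_indices: tuple[int, ...]
    name: str
    residue_number: int

    @property
    def is_pseudo(self) -> bool:
        return len(self.atom_indices) > 1 or self.name.startswith("Q")

    @property
    def multiplicity(self) -> int:
        return len(self.atom_indices)

    def position(self, positions: np.ndarray) -> np.ndarray:
        return positions[list(self.atom_indices)].mean(axis=0)


@dataclass
class RawEntry:
    source_line: int
    residue_i: int = 0
    residue_name_i: str = ""
    atom_name_i: str = ""
    residue_j: int = 0
    residue_name_j: str = ""
    atom_name_j: str = ""
    upper: float = 0.0
    error: str | None = None


@dataclass
class DistanceRestraint:
    residue_i: int
    atom_name_i: str
    residue_j: int
    atom_name_j: str
    endpoint_i: Endpoint
    endpoint_j: Endpoint
    r_p: float
    r_corrected: float
    source_line: int
    notes: list[str] = field(default_factory=list)

    def distance(self, positions: np.ndarray) -> float:
        return float(
            np.linalg.norm(
                self.endpoint_i.position(positions) - self.endpoint_j.position(positions)
            )
        )


@dataclass
class RestraintSet:
    restraints: list[DistanceRestraint] = field(default_factory=list)
    unresolved: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_entries(self) -> int:
        return len(self.restraints) + len(self.unresolved)


# ---------------------------------------------------------------------------
# pseudoatom construction
# ---------------------------------------------------------------------------

_H_GROUP = re.compile(r"^H(.*)([123])$")


def build_pseudoatoms(model_atoms: list[Atom]) -> list[Pseudoatom]:
    """Apply the Q / QX / QQX naming rules per residue."""
    residues: dict[tuple[str, int], list[int]] = {}
    for idx, atom in enumerate(model_atoms):
        if atom.is_hydrogen:
            residues.setdefault((atom.chain_id, atom.residue_number), []).append(idx)

    pseudoatoms: list[Pseudoatom] = []
    for (chain, resnum), h_indices in sorted(residues.items()):
        groups: dict[str, list[int]] = {}
        for idx in h_indices:
            m = _H_GROUP.match(model_atoms[idx].name)
            if m:
                groups.setdefault(m.group(1), []).append(idx)
        for stem in sorted(groups):
            name = "Q" + stem  # stem "" -> "Q"
            pseudoatoms.append(Pseudoatom(name, resnum, sorted(groups[stem]), chain))
        # QQX from the union of QX1 and QX2 parent sets
        bases = {s[:-1] for s in groups if s and s[-1] in "12"}
        for base in sorted(bases):
            if base and (base + "1") in groups and (base + "2") in groups:
                parents = sorted(groups[base + "1"] + groups[base + "2"])
                pseudoatoms.append(Pseudoatom("QQ" + base, resnum, parents, chain))
    return pseudoatoms


# ---------------------------------------------------------------------------
# parsing and correction
# ---------------------------------------------------------------------------

def parse_upl(upl_text: str) -> list[RawEntry]:
    """Parse .upl text; malformed lines become entries with ``error`` set."""
    entries: list[RawEntry] = []
    for line_no, line in enumerate(upl_text.splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        tokens = body.split()
        try:
            if len(tokens) < 7:
                raise ValueError("fewer than 7 fields")
            entry = RawEntry(
                source_line=line_no,
                residue_i=int(tokens[0]),
                residue_name_i=tokens[1],
                atom_name_i=tokens[2],
                residue_j=int(tokens[3]),
                residue_name_j=tokens[4],
                atom_name_j=tokens[5],
                upper=float(tokens[6]),
            )
            if entry.upper <= 0:
                raise ValueError(f"nonpositive upper limit {entry.upper}")
        except ValueError as exc:
            entries.append(RawEntry(source_line=line_no, error=f"parse error: {exc}"))
            continue
        entries.append(entry)
    return entries


def correct_pseudoatom_distance(r_p: float, n_i: int, n_j: int) -> float:
    """Widen an upper limit for proton degeneracy: r_p * (n_i * n_j)^(1/6)."""
    if r_p <= 0:
        raise ValueError(f"upper limit must be positive, got {r_p}")
    if n_i < 1 or n_j < 1:
        raise ValueError(f"multiplicities must be >= 1, got {n_i}, {n_j}")
    return r_p * float(n_i * n_j) ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# resolution
# ---------------------------------------------------------------------------

def resolve(
    entries: list[RawEntry],
    atoms: list[Atom],
    pseudoatoms: list[Pseudoatom],
    bond_graph=None,
) -> RestraintSet:
    """Match raw entries to atoms/pseudoatoms and apply limit corrections.

    Real atoms shadow pseudoatoms of the same name.  A residue-name
    mismatch between file and structure produces a warning but the match
    proceeds on residue number plus atom name.  When a bond graph is
    supplied, restraints between identical or 1-2/1-3-bonded endpoints are
    kept but annotated.
    """
    atom_lookup: dict[tuple[int, str], int] = {}
    res_names: dict[int, str] = {}
    for idx, atom in enumerate(atoms):
        atom_lookup.setdefault((atom.residue_number, atom.name), idx)
        res_names.setdefault(atom.residue_number, atom.residue_name)
    pseudo_lookup: dict[tuple[int, str], Pseudoatom] = {}
    for p in pseudoatoms:
        pseudo_lookup.setdefault((p.residue_number, p.name), p)

    result = RestraintSet()

    def find(resnum: int, name: str) -> Endpoint | None:
        idx = atom_lookup.get((resnum, name))
        if idx is not None:
            return Endpoint((idx,), name, resnum)
        p = pseudo_lookup.get((resnum, name))
        if p is not None:
            return Endpoint(tuple(p.parent_hydrogen_indices), name, resnum)
        return None

    for entry in entries:
        if entry.error is not None:
            result.unresolved.append((entry.source_line, entry.error))
            continue
        ep_i = find(entry.residue_i, entry.atom_name_i)
        ep_j = find(entry.residue_j, entry.atom_name_j)
        if ep_i is None or ep_j is None:
            bad = (
                (entry.atom_name_i, entry.residue_i)
                if ep_i is None
                else (entry.atom_name_j, entry.residue_j)
            )
            result.unresolved.append(
                (entry.source_line, f"unknown atom {bad[0]} in residue {bad[1]}")
            )
            continue
        for resnum, resname in (
            (entry.residue_i, entry.residue_name_i),
            (entry.residue_j, entry.residue_name_j),
        ):
            actual = res_names.get(resnum)
            if actual is not None and actual != resname:
                result.warnings.append(
                    f"line {entry.source_line}: residue {resnum} is {actual} "
                    f"in structure but {resname} in restraint file"
                )
        restraint = DistanceRestraint(
            residue_i=entry.residue_i,
            atom_name_i=entry.atom_name_i,
            residue_j=entry.residue_j,
            atom_name_j=entry.atom_name_j,
            endpoint_i=ep_i,
            endpoint_j=ep_j,
            r_p=entry.upper,
            r_corrected=correct_pseudoatom_distance(
                entry.upper, ep_i.multiplicity, ep_j.multiplicity
            ),
            source_line=entry.source_line,
        )
        if set(ep_i.atom_indices) & set(ep_j.atom_indices):
            restraint.notes.append("endpoints share atoms")
        elif bond_graph is not None and ep_i.multiplicity == ep_j.multiplicity == 1:
            d = bond_graph.topological_distance(
                ep_i.atom_indices[0], ep_j.atom_indices[0], cap=2
            )
            if d in (1, 2):
                restraint.notes.append(f"endpoints are 1-{d + 1} bonded")
        result.restraints.append(restraint)
    return result


def load_upl(
    upl_text: str, atoms: list[Atom], bond_graph=None
) -> RestraintSet:
    """Convenience: parse + build pseudoatoms + resolve in one call."""
    return resolve(parse_upl(upl_text), atoms, build_pseudoatoms(atoms), bond_graph)


def format_restraints_log(restraint_set: RestraintSet) -> str:
    """The restraints.log payload: one line per unresolved entry."""
    lines = [
        f"line {line_no}: {reason}"
        for line_no, reason in sorted(restraint_set.unresolved)
    ]
    return "\n".join(lines) + ("\n" if lines else "")
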