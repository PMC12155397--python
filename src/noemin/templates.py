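"""Residue bond templates for the 20 standard amino acids.

Heavy-atom connectivity is stored explicitly as (name_a, name_b, order,
aromatic).  Hydrogens are attached by name: for a hydrogen ``H<rest>`` the
parent heavy atom is the one named ``C<rest>``, ``N<rest>``, ``O<rest>`` or
``S<rest>``, trying first the full remainder and then the remainder with
trailing digits stripped (so HB2 -> CB, HG11 -> CG1, HE21 -> NE2, H -> N).
The table is regenerable from any chemical-component dictionary; orders use
1.5 for resonant/aromatic bonds and 1.41 for amides.
"""

from __future__ import annotations

__all__ = [
    "STANDARD_RESIDUES",
    "RESIDUE_BONDS",
    "BACKBONE_BONDS",
    "AMIDE_BOND_ORDER",
    "hydrogen_parent",
    "template_bonds",
]

AMIDE_BOND_ORDER = 1.41

# (name_a, name_b, order, aromatic) shared by every standard residue
BACKBONE_BONDS: list[tuple[str, str, float, bool]] = [
    ("N", "CA", 1.0, False),
    ("CA", "C", 1.0, False),
    ("C", "O", 2.0, False),
    ("C", "OXT", 1.5, False),
]

_AROM = True

_SIDE_CHAINS: dict[str, list[tuple[str, str, float, bool]]] = {
    "ALA": [("CA", "CB", 1.0, False)],
    "ARG": [
        ("CA", "CB", 1.0, False), ("CB", "CG", 1.0, False),
        ("CG", "CD", 1.0, False), ("CD", "NE", 1.0, False),
        ("NE", "CZ", 1.5, False), ("CZ", "NH1", 1.5, False),
        ("CZ", "NH2", 1.5, False),
    ],
    "ASN": [
        ("CA", "CB", 1.0, False), ("CB", "CG", 1.0, False),
        ("CG", "OD1", 2.0, False), ("CG", "ND2", AMIDE_BOND_ORDER, False),
    ],
    "ASP": [
        ("CA", "CB", 1.0, False), ("CB", "CG", 1.0, False),
        ("CG", "OD1", 1.5, False), ("CG", "OD2", 1.5, False),
    ],
    "CYS": [("CA", "CB", 1.0, False), ("CB", "SG", 1.0, False)],
    "GLN": [
        ("CA", "CB", 1.0, False), ("CB", "CG", 1.0, False),
        ("CG", "CD", 1.0, False), ("CD", "OE1", 2.0, False),
        ("CD", "NE2", AMIDE_BOND_ORDER, False),
    ],
    "GLU": [
        ("CA", "CB", 1.0, False), ("CB", "CG", 1.0, False),
        ("CG", "CD", 1.0, False), ("CD", "OE1", 1.5, False),
        ("CD", "OE2", 1.5, False),
    ],
    "GLY": [],
    "HIS": [
        ("CA", "CB", 1.0, False), ("CB", "CG", 1.0, False),
        ("CG", "ND1", 1.5, _AROM), ("CG", "CD2", 1.5, _AROM),
        ("ND1", "CE1", 1.5, _AROM), ("CD2", "NE2", 1.5, _AROM),
        ("CE1", "NE2", 1.5, _AROM),
    ],
    "ILE": [
        ("CA", "CB", 1.0, False), ("CB", "CG1", 1.0, False),
        ("CB", "CG2", 1.0, False), ("CG1", "CD1", 1.0, False),
    ],
    "LEU": [
        ("CA", "CB", 1.0, False), ("CB", "CG", 1.0, False),
        ("CG", "CD1", 1.0, False), ("CG", "CD2", 1.0, False),
    ],
    "LYS": [
        ("CA", "CB", 1.0, False), ("CB", "CG", 1.0, False),
        ("CG", "CD", 1.0, False), ("CD", "CE", 1.0, False),
        ("CE", "NZ", 1.0, False),
    ],
    "MET": [
        ("CA", "CB", 1.0, False), ("CB", "CG", 1.0, False),
        ("CG", "SD", 1.0, False), ("SD", "CE", 1.0, False),
    ],
    "PHE": [
        ("CA", "CB", 1.0, False), ("CB", "CG", 1.0, False),
        ("CG", "CD1", 1.5, _AROM), ("CG", "CD2", 1.5, _AROM),
        ("CD1", "CE1", 1.5, _AROM), ("CD2", "CE2", 1.5, _AROM),
        ("CE1", "CZ", 1.5, _AROM), ("CE2", "CZ", 1.5, _AROM),
    ],
    "PRO": [
        ("CA", "CB", 1.0, False), ("CB", "CG", 1.0, False),
        ("CG", "CD", 1.0, False), ("CD", "N", 1.0, False),
    ],
    "SER": [("CA", "CB", 1.0, False), ("CB", "OG", 1.0, False)],
    "THR": [
        ("CA", "CB", 1.0, False), ("CB", "OG1", 1.0, False),
        ("CB", "CG2", 1.0, False),
    ],
    "TRP": [
        ("CA", "CB", 1.0, False), ("CB", "CG", 1.0, False),
        ("CG", "CD1", 1.5, _AROM), ("CG", "CD2", 1.5, _AROM),
        ("CD1", "NE1", 1.5, _AROM), ("NE1", "CE2", 1.5, _AROM),
        ("CD2", "CE2", 1.5, _AROM), ("CD2", "CE3", 1.5, _AROM),
        ("CE3", "CZ3", 1.5, _AROM), ("CZ3", "CH2", 1.5, _AROM),
        ("CH2", "CZ2", 1.5, _AROM), ("CZ2", "CE2", 1.5, _AROM),
    ],
    "TYR": [
        ("CA", "CB", 1.0, False), ("CB", "CG", 1.0, False),
        ("CG", "CD1", 1.5, _AROM), ("CG", "CD2", 1.5, _AROM),
        ("CD1", "CE1", 1.5, _AROM), ("CD2", "CE2", 1.5, _AROM),
        ("CE1", "CZ", 1.5, _AROM), ("CE2", "CZ", 1.5, _AROM),
        ("CZ", "OH", 1.0, False),
    ],
    "VAL": [
        ("CA", "CB", 1.0, False), ("CB", "CG1", 1.0, False),
        ("CB", "CG2", 1.0, False),
    ],
}

STANDARD_RESIDUES = frozenset(_SIDE_CHAINS)

RESIDUE_BONDS: dict[str, list[tuple[str, str, float, bool]]] = {
    res: BACKBONE_BONDS + side for res, side in _SIDE_CHAINS.items()
}


def template_bonds(residue_name: str) -> list[tuple[str, str, float, bool]] | None:
    """Bond template for a standard residue, or None for unknown residues."""
    return RESIDUE_BONDS.get(residue_name)


def hydrogen_parent(h_name: str, heavy_names: set[str]) -> str | None:
    """Resolve the parent heavy-atom name of a hydrogen by naming convention.

    Tries ``<X><rest>`` for X in C, N, O, S with the full remainder first,
    then with trailing digits progressively stripped.  ``H``/``H1``..``H3``
    map to the backbone ``N``; ``HXT`` maps to ``OXT``.
    """
    if not h_name.startswith("H"):
        return None
    if h_name == "HXT":
        return "OXT" if "OXT" in heavy_names else None
    rest = h_name[1:]
    candidates = [rest]
    trimmed = rest
    while trimmed and trimmed[-1].isdigit():
        trimmed = trimmed[:-1]
        candidates.append(trimmed)
    for cand in candidates:
        if cand == "":
            if "N" in heavy_names:
                return "N"
            continue
        for heavy_prefix in ("C", "N", "O", "S"):
            name = heavy_prefix + cand
            if name in heavy_names:
                return name
    return None
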