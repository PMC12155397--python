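"""Multi-model PDB reading and writing for NMR ensembles.

The reader understands MODEL/ENDMDL blocks (or one bare coordinate block),
loads ATOM and, optionally, HETATM records, and can rewrite legacy
digit-prefixed hydrogen names ("1HB2" -> "HB21") to the canonical
digit-suffixed form that restraint matching relies on.  The writer emits
fixed-column PDB v3.3 with coordinates at three decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .model import Atom, Ensemble, EnsembleConsistencyError, Model

__all__ = [
    "HydrogenNameStyle",
    "PdbDialectConfig",
    "PdbFormatError",
    "read_ensemble",
    "write_ensemble",
]

# Two-letter element symbols that plausibly appear in biomolecular PDB
# files; used only for HETATM name-based element inference.
_TWO_LETTER_ELEMENTS = {
    "HE", "LI", "BE", "NE", "NA", "MG", "AL", "SI", "CL", "AR", "CA",
    "MN", "FE", "CO", "NI", "CU", "ZN", "SE", "BR", "MO", "CD", "PT", "AU", "HG",
}


class PdbFormatError(ValueError):
    """Malformed or empty PDB input / unwritable atom record."""


class HydrogenNameStyle(str, Enum):
    AS_IS = "as_is"
    NORMALIZE_DIGIT_PREFIX = "normalize_digit_prefix"


@dataclass
class PdbDialectConfig:
    hydrogen_name_style: HydrogenNameStyle = HydrogenNameStyle.NORMALIZE_DIGIT_PREFIX
    keep_hetero: bool = True


def _normalize_name(name: str) -> str:
    """Move a leading digit to the end: '1HB' -> 'HB1', '2HG1' -> 'HG12'."""
    if name and name[0].isdigit():
        return name[1:] + name[0]
    return name


def _infer_element(name: str, hetero: bool) -> str:
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise PdbFormatError(f"cannot infer element from atom name {name!r}")
    if hetero and stripped[:2].upper() in _TWO_LETTER_ELEMENTS:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def read_ensemble(pdb_text: str, config: PdbDialectConfig | None = None) -> Ensemble:
    """Parse PDB text into an :class:`Ensemble` (one Model per MODEL block).

    A file without MODEL records yields exactly one model.  Raises
    :class:`PdbFormatError` on zero atoms and
    :class:`EnsembleConsistencyError` when models disagree on their atom
    lists.
    """
    config = config or PdbDialectConfig()
    normalize = config.hydrogen_name_style == HydrogenNameStyle.NORMALIZE_DIGIT_PREFIX

    models: list[Model] = []
    atoms: list[Atom] = []
    coords: list[list[float]] = []
    in_model = False

    def _flush() -> None:
        nonlocal atoms, coords
        if atoms:
            models.append(Model(atoms, np.array(coords)))
        atoms, coords = [], []

    for line in pdb_text.splitlines():
        record = line[:6].strip()
        if record == "MODEL":
            _flush()
            in_model = True
        elif record == "ENDMDL":
            _flush()
            in_model = False
        elif record in ("ATOM", "HETATM"):
            hetero = record == "HETATM"
            if hetero and not config.keep_hetero:
                continue
            line = line.ljust(80)
            name = line[12:16].strip()
            if normalize:
                name = _normalize_name(name)
            element_field = line[76:78].strip()
            element = (
                element_field.capitalize()
                if element_field
                else _infer_element(name, hetero)
            )
            try:
                serial = int(line[6:11])
            except ValueError:
                serial = len(atoms) + 1
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_name=line[17:20].strip(),
                    residue_number=int(line[22:26]),
                    chain_id=line[21].strip() or "A",
                    is_hetero=hetero,
                )
            )
            coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    _flush()

    if not models:
        raise PdbFormatError("no atoms found in PDB input")
    return Ensemble(models)  # raises EnsembleConsistencyError on mismatch


def _format_name(atom: Atom) -> str:
    """PDB column-13..16 name placement.

    Names of 1-3 characters whose element symbol is a single letter start
    in column 14; 4-character names fill the whole field.
    """
    name = atom.name
    if len(name) > 4:
        raise PdbFormatError(f"atom name {name!r} longer than 4 characters")
    if len(name) == 4 or len(atom.element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_ensemble(ensemble: Ensemble, added_atoms_flagged: bool = False) -> str:
    """Serialize an ensemble as fixed-column multi-model PDB text.

    Serial numbers are renumbered sequentially per model.  When
    ``added_atoms_flagged`` is set, atoms whose serial is 0 in the source
    model (a convention used by terminus fixing) keep a ``REMARK`` notice.
    """
    lines: list[str] = []
    added: list[str] = []
    for model_no, model in enumerate(ensemble.models, start=1):
        lines.append(f"MODEL     {model_no:>4d}")
        for serial, (atom, pos) in enumerate(zip(model.atoms, model.positions), start=1):
            record = "HETATM" if atom.is_hetero else "ATOM  "
            lines.append(
                f"{record}{serial:>5d} {_format_name(atom)} "
                f"{atom.residue_name:>3s} {atom.chain_id:1s}{atom.residue_number:>4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element.upper():>2s}"
            )
            if added_atoms_flagged and atom.serial == 0 and model_no == 1:
                added.append(atom.name)
        lines.append("ENDMDL")
    if added:
        lines.insert(0, "REMARK   3 ATOMS ADDED BY TERMINUS FIXING: " + " ".join(added))
    lines.append("END")
    return "\n".join(lines) + "\n"
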