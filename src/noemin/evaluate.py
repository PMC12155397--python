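"""Post-minimization quality metrics.

The target function here is the plain sum of squared upper-limit
violations (A^2) over resolved restraints, with pseudoatom distances taken
from mean-parent positions and corrected limits.  It is deliberately
unweighted and is NOT claimed to be numerically identical to any external
program's target function.  The clash metric counts van der Waals overlaps
of at least 0.4 A between topologically distant pairs, per 1000 atoms; it
is an approximate clash count, not a validation-server score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import BEYOND_CAP, Ensemble
from .perception import TypedSystem
from .restraints import RestraintSet

__all__ = [
    "ViolationReport",
    "ViolationRow",
    "target_function",
    "clash_count",
    "violation_report",
    "VDW_RADII",
]

CLASH_OVERLAP = 0.4        # A of vdW overlap that counts as a clash
MIN_BOND_SEPARATION = 4    # pairs closer than this many bonds are exempt

# Bondi-style van der Waals radii (A); unlisted elements default to 1.5.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Ne": 1.54, "Na": 2.27, "Mg": 1.73, "P": 1.80, "S": 1.80, "Cl": 1.75,
    "Ar": 1.88, "K": 2.75, "Ca": 2.31, "Fe": 2.00, "Zn": 1.39, "Se": 1.90,
    "Br": 1.85, "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.5


@dataclass
class ViolationRow:
    model_index: int
    source_line: int
    residue_i: int
    atom_name_i: str
    residue_j: int
    atom_name_j: str
    upper_corrected: float
    distance: float
    violation: float

    @property
    def satisfied(self) -> bool:
        return self.violation <= 0.0


@dataclass
class ViolationReport:
    rows: list[ViolationRow]
    per_model_tf: list[float]
    clashes_per_1000: list[float] | None = None

    @property
    def mean_tf(self) -> float:
        return float(np.mean(self.per_model_tf)) if self.per_model_tf else 0.0

    @property
    def max_violation(self) -> float:
        return max((r.violation for r in self.rows), default=0.0)

    def worst(self, n: int = 10) -> list[ViolationRow]:
        return sorted(self.rows, key=lambda r: -r.violation)[:n]

    def to_tsv(self) -> str:
        header = (
            "model\tline\tresidue_i\tatom_i\tresidue_j\tatom_j"
            "\tupper_corrected\tdistance\tviolation\tsatisfied"
        )
        lines = [header]
        for r in self.rows:
            lines.append(
                f"{r.model_index + 1}\t{r.source_line}\t{r.residue_i}\t{r.atom_name_i}"
                f"\t{r.residue_j}\t{r.atom_name_j}\t{r.upper_corrected:.3f}"
                f"\t{r.distance:.3f}\t{r.violation:.3f}\t{int(r.satisfied)}"
            )
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        n_models = len(self.per_model_tf)
        n_restraints = len(self.rows) // n_models if n_models else 0
        lines = [
            f"restraints evaluated: {n_restraints}",
            f"models: {n_models}",
            f"target function per model (A^2): "
            + " ".join(f"{tf:.4f}" for tf in self.per_model_tf),
            f"mean target function (A^2): {self.mean_tf:.4f}",
            f"max violation (A): {self.max_violation:.3f}",
        ]
        if self.clashes_per_1000 is not None:
            lines.append(
                "approximate clash count per 1000 atoms per model: "
                + " ".join(f"{c:.1f}" for c in self.clashes_per_1000)
            )
        return "\n".join(lines) + "\n"


def target_function(positions: np.ndarray, restraint_set: RestraintSet) -> float:
    """Sum of squared upper-limit violations (A^2) for one model."""
    tf = 0.0
    for restraint in restraint_set.restraints:
        v = max(0.0, restraint.distance(positions) - restraint.r_corrected)
        tf += v * v
    return tf


def clash_count(system: TypedSystem, model_index: int = 0) -> float:
    """Approximate steric clashes per 1000 atoms for one model.

    Counts unordered pairs at topological distance >= 4 bonds (or in
    disconnected components) whose separation is more than 0.4 A inside
    the sum of their vdW radii.
    """
    atoms = system.atoms
    pos = system.ensemble.models[model_index].positions
    graph = system.bonds
    n = len(atoms)
    if n == 0:
        return 0.0
    radii = np.array(
        [VDW_RADII.get(a.element.capitalize(), DEFAULT_VDW_RADIUS) for a in atoms]
    )
    clashes = 0
    for i in range(n):
        for j in range(i + 1, n):
            threshold = radii[i] + radii[j] - CLASH_OVERLAP
            if np.linalg.norm(pos[i] - pos[j]) >= threshold:
                continue
            topo = graph.topological_distance(i, j, cap=MIN_BOND_SEPARATION - 1)
            if topo == BEYOND_CAP:  # >= 4 bonds away or disconnected
                clashes += 1
    return clashes * 1000.0 / n


def violation_report(
    ensemble: Ensemble,
    restraint_set: RestraintSet,
    system: TypedSystem | None = None,
) -> ViolationReport:
    """Per-restraint, per-model distances, violations and satisfied flags."""
    rows: list[ViolationRow] = []
    per_model_tf: list[float] = []
    for m_idx, model in enumerate(ensemble.models):
        tf = 0.0
        for restraint in restraint_set.restraints:
            d = restraint.distance(model.positions)
            v = max(0.0, d - restraint.r_corrected)
            tf += v * v
            rows.append(
                ViolationRow(
                    model_index=m_idx,
                    source_line=restraint.source_line,
                    residue_i=restraint.residue_i,
                    atom_name_i=restraint.atom_name_i,
                    residue_j=restraint.residue_j,
                    atom_name_j=restraint.atom_name_j,
                    upper_corrected=restraint.r_corrected,
                    distance=d,
                    violation=v,
                )
            )
        per_model_tf.append(tf)
    clashes = None
    if system is not None:
        clashes = [clash_count(system, m) for m in range(ensemble.n_models)]
    return ViolationReport(rows=rows, per_model_tf=per_model_tf, clashes_per_1000=clashes)
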