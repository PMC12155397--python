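"""Deterministic toy molecules, ensembles and .upl files for testing.

Every builder returns idealized geometry (tetrahedral/planar as chemically
appropriate) with an optional seeded uniform per-coordinate perturbation,
so the whole pipeline is exercisable without external data.  Restraint
fixtures also emit matching .upl text whose limits are violated by a known
margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import Atom, Ensemble, Model

__all__ = ["FixtureSpec", "build_fixture", "FixtureError"]

FIXTURE_KINDS = (
    "acetate",
    "methylguanidinium",
    "ala_tripeptide",
    "gly_dipeptide",
    "valine_residue",
    "diatomic",
    "two_atom_restraint_case",
)


class FixtureError(ValueError):
    """Unknown fixture kind or invalid parameters."""


@dataclass
class FixtureSpec:
    kind: str
    distortion_amplitude: float = 0.0
    seed: int = 0
    n_models: int = 1
    # diatomic / two-atom extras
    elements: tuple[str, str] = ("H", "H")
    separation: float = 0.74
    upper_limit: float = 2.5
    initial_distance: float = 6.0

    def __post_init__(self) -> None:
        if self.distortion_amplitude < 0:
            raise FixtureError("distortion amplitude must be >= 0")
        if self.kind not in FIXTURE_KINDS:
            raise FixtureError(f"unknown fixture kind {self.kind!r}")


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: new atom d with |d-c| = bond, angle(b,c,d) and
    torsion(a,b,c,d) as requested."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:  # collinear reference: pick any perpendicular
        n = np.cross(np.array([0.0, 0.0, 1.0]), bc)
        nn = np.linalg.norm(n)
        if nn < 1e-10:
            n = np.cross(np.array([0.0, 1.0, 0.0]), bc)
            nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.cos(torsion) * math.sin(angle),
            bond * math.sin(torsion) * math.sin(angle),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _atoms(rows: list[tuple[str, str, str, int, bool]], coords: list) -> tuple[list[Atom], np.ndarray]:
    atoms = [
        Atom(
            serial=i + 1, name=name, element=element,
            residue_name=resname, residue_number=resnum,
            chain_id="A", is_hetero=hetero,
        )
        for i, (name, element, resname, resnum, hetero) in enumerate(rows)
    ]
    return atoms, np.array(coords, dtype=float)


# ---------------------------------------------------------------------------
# individual molecules
# ---------------------------------------------------------------------------

def _acetate() -> tuple[list[Atom], np.ndarray]:
    """Planar CH3-COO(-), both C-O ~1.26 A."""
    c = np.zeros(3)
    ch3 = np.array([-1.50, 0.0, 0.0])
    phi = math.radians(63.0)  # O-C-O ~ 126 deg
    o1 = 1.26 * np.array([math.cos(phi), math.sin(phi), 0.0])
    o2 = 1.26 * np.array([math.cos(phi), -math.sin(phi), 0.0])
    h = [
        _place(o1, c, ch3, 1.09, 109.47, t) for t in (60.0, 180.0, 300.0)
    ]
    rows = [
        ("C", "C", "ACT", 1, True),
        ("O", "O", "ACT", 1, True),
        ("OXT", "O", "ACT", 1, True),
        ("CH3", "C", "ACT", 1, True),
        ("H1", "H", "ACT", 1, True),
        ("H2", "H", "ACT", 1, True),
        ("H3", "H", "ACT", 1, True),
    ]
    return _atoms(rows, [c, o1, o2, ch3, *h])


def _methylguanidinium() -> tuple[list[Atom], np.ndarray]:
    """Planar guanidinium with a methyl cap on NE, named like an ARG tail."""
    cz = np.zeros(3)
    ne = np.array([1.35, 0.0, 0.0])
    nh1 = 1.35 * np.array([math.cos(math.radians(120)), math.sin(math.radians(120)), 0.0])
    nh2 = 1.35 * np.array([math.cos(math.radians(240)), math.sin(math.radians(240)), 0.0])
    cd = _place(nh1, cz, ne, 1.46, 123.0, 180.0)
    he = _place(nh1, cz, ne, 1.01, 117.0, 0.0)
    hh11 = _place(ne, cz, nh1, 1.01, 120.0, 0.0)
    hh12 = _place(ne, cz, nh1, 1.01, 120.0, 180.0)
    hh21 = _place(ne, cz, nh2, 1.01, 120.0, 0.0)
    hh22 = _place(ne, cz, nh2, 1.01, 120.0, 180.0)
    hd = [_place(cz, ne, cd, 1.09, 109.47, t) for t in (60.0, 180.0, 300.0)]
    rows = [
        ("CZ", "C", "ARG", 1, False),
        ("NE", "N", "ARG", 1, False),
        ("NH1", "N", "ARG", 1, False),
        ("NH2", "N", "ARG", 1, False),
        ("CD", "C", "ARG", 1, False),
        ("HE", "H", "ARG", 1, False),
        ("HH11", "H", "ARG", 1, False),
        ("HH12", "H", "ARG", 1, False),
        ("HH21", "H", "ARG", 1, False),
        ("HH22", "H", "ARG", 1, False),
        ("HD1", "H", "ARG", 1, False),
        ("HD2", "H", "ARG", 1, False),
        ("HD3", "H", "ARG", 1, False),
    ]
    return _atoms(rows, [cz, ne, nh1, nh2, cd, he, hh11, hh12, hh21, hh22, *hd])


def _peptide(sequence: list[str]) -> tuple[list[Atom], np.ndarray]:
    """Extended-backbone peptide from ALA/GLY residues.

    The N terminus carries a single amide-style H and the C terminus lacks
    OXT, mimicking a torsion-angle-dynamics output that terminus fixing is
    supposed to complete.
    """
    rows: list[tuple[str, str, str, int, bool]] = []
    coords: list[np.ndarray] = []

    def add(name: str, element: str, resname: str, resnum: int, pos: np.ndarray) -> None:
        rows.append((name, element, resname, resnum, False))
        coords.append(pos)

    phi, psi, omega = 180.0, 180.0, 180.0
    n_prev = ca_prev = c_prev = None
    for i, resname in enumerate(sequence, start=1):
        if i == 1:
            n = np.zeros(3)
            ca = np.array([1.458, 0.0, 0.0])
            ang = math.radians(180.0 - 110.4)
            c = ca + 1.525 * np.array([math.cos(ang), math.sin(ang), 0.0])
        else:
            n = _place(n_prev, ca_prev, c_prev, 1.33, 116.6, psi)
            ca = _place(ca_prev, c_prev, n, 1.458, 121.7, omega)
            c = _place(c_prev, n, ca, 1.525, 110.4, phi)
        add("N", "N", resname, i, n)
        add("CA", "C", resname, i, ca)
        add("C", "C", resname, i, c)
        o_torsion = 0.0 if i == len(sequence) else psi + 180.0
        add("O", "O", resname, i, _place(n, ca, c, 1.231, 120.5, o_torsion))
        if i == 1:
            add("H", "H", resname, i, _place(c, ca, n, 1.01, 109.5, 60.0))
        else:
            add("H", "H", resname, i, _place(ca_prev, c_prev, n, 1.01, 119.0, 180.0))
        if resname == "GLY":
            add("HA2", "H", resname, i, _place(c, n, ca, 1.09, 109.5, 120.0))
            add("HA3", "H", resname, i, _place(c, n, ca, 1.09, 109.5, 240.0))
        else:
            add("HA", "H", resname, i, _place(c, n, ca, 1.09, 109.5, 118.0))
            cb = _place(c, n, ca, 1.53, 110.5, 240.0)
            add("CB", "C", resname, i, cb)
            for k, t in enumerate((60.0, 180.0, 300.0), start=1):
                add(f"HB{k}", "H", resname, i, _place(n, ca, cb, 1.09, 109.47, t))
        n_prev, ca_prev, c_prev = n, ca, c
    return _atoms(rows, coords)


def _valine() -> tuple[list[Atom], np.ndarray]:
    rows: list[tuple[str, str, str, int, bool]] = []
    coords: list[np.ndarray] = []

    def add(name: str, element: str, pos: np.ndarray) -> None:
        rows.append((name, element, "VAL", 1, False))
        coords.append(pos)

    n = np.zeros(3)
    ca = np.array([1.458, 0.0, 0.0])
    ang = math.radians(180.0 - 110.4)
    c = ca + 1.525 * np.array([math.cos(ang), math.sin(ang), 0.0])
    add("N", "N", n)
    add("CA", "C", ca)
    add("C", "C", c)
    add("O", "O", _place(n, ca, c, 1.231, 120.5, 0.0))
    add("H", "H", _place(c, ca, n, 1.01, 109.5, 60.0))
    add("HA", "H", _place(c, n, ca, 1.09, 109.5, 118.0))
    cb = _place(c, n, ca, 1.53, 110.5, 240.0)
    add("CB", "C", cb)
    add("HB", "H", _place(n, ca, cb, 1.09, 109.47, 60.0))
    cg1 = _place(n, ca, cb, 1.53, 110.5, 180.0)
    cg2 = _place(n, ca, cb, 1.53, 110.5, 300.0)
    add("CG1", "C", cg1)
    add("CG2", "C", cg2)
    for k, t in enumerate((60.0, 180.0, 300.0), start=1):
        add(f"HG1{k}", "H", _place(ca, cb, cg1, 1.09, 109.47, t))
    for k, t in enumerate((60.0, 180.0, 300.0), start=1):
        add(f"HG2{k}", "H", _place(ca, cb, cg2, 1.09, 109.47, t))
    return _atoms(rows, coords)


def _diatomic(spec: FixtureSpec) -> tuple[list[Atom], np.ndarray]:
    el_i, el_j = spec.elements
    rows = [
        (f"{el_i.upper()}1", el_i.capitalize(), "LIG", 1, True),
        (f"{el_j.upper()}2", el_j.capitalize(), "LIG", 1, True),
    ]
    coords = [[0.0, 0.0, 0.0], [spec.separation, 0.0, 0.0]]
    return _atoms(rows, coords)


def _two_atom_restraint(spec: FixtureSpec) -> tuple[list[Atom], np.ndarray, str]:
    el_i, el_j = spec.elements
    rows = [
        (f"{el_i.upper()}1", el_i.capitalize(), "LIG", 1, True),
        (f"{el_j.upper()}1", el_j.capitalize(), "LIG", 2, True),
    ]
    coords = [[0.0, 0.0, 0.0], [spec.initial_distance, 0.0, 0.0]]
    atoms, pos = _atoms(rows, coords)
    upl = (
        f"  1 LIG {atoms[0].name:<5s} 2 LIG {atoms[1].name:<5s} "
        f"{spec.upper_limit:6.2f}\n"
    )
    return atoms, pos, upl


# ---------------------------------------------------------------------------
# entry point
# ---------------------------------------------------------------------------

def build_fixture(spec: FixtureSpec) -> tuple[Ensemble, str | None]:
    """Build the requested fixture, optionally distorted per model."""
    upl_text: str | None = None
    if spec.kind == "acetate":
        atoms, pos = _acetate()
    elif spec.kind == "methylguanidinium":
        atoms, pos = _methylguanidinium()
    elif spec.kind == "ala_tripeptide":
        atoms, pos = _peptide(["ALA", "ALA", "ALA"])
        upl_text = _peptide_upl(atoms, pos)
    elif spec.kind == "gly_dipeptide":
        atoms, pos = _peptide(["GLY", "GLY"])
    elif spec.kind == "valine_residue":
        atoms, pos = _valine()
    elif spec.kind == "diatomic":
        atoms, pos = _diatomic(spec)
    elif spec.kind == "two_atom_restraint_case":
        atoms, pos, upl_text = _two_atom_restraint(spec)
    else:  # pragma: no cover - guarded by FixtureSpec
        raise FixtureError(f"unknown fixture kind {spec.kind!r}")

    rng = np.random.default_rng(spec.seed)
    models = []
    for _ in range(spec.n_models):
        if spec.distortion_amplitude > 0:
            noise = rng.uniform(
                -spec.distortion_amplitude, spec.distortion_amplitude, pos.shape
            )
        else:
            noise = 0.0
        models.append(Model(atoms, pos + noise))
    return Ensemble(models), upl_text


def _peptide_upl(atoms, pos) -> str:
    """Backbone restraints for the ALA tripeptide, violated by ~0.5-1 A.

    Limits are set tighter than the built geometry by a stated margin so
    that restrained minimization has work to do, plus one methyl
    pseudoatom entry exercising the N^(1/6) correction.
    """
    by = {(a.residue_number, a.name): i for i, a in enumerate(atoms)}
    lines = []
    for (ri, ni), (rj, nj), slack in [
        ((1, "CA"), (3, "CA"), -1.0),
        ((1, "N"), (3, "C"), -1.0),
    ]:
        d = float(np.linalg.norm(pos[by[(ri, ni)]] - pos[by[(rj, nj)]]))
        lines.append(
            f"{ri:>4d} {atoms[by[(ri, ni)]].residue_name:<4s} {ni:<5s}"
            f"{rj:>4d} {atoms[by[(rj, nj)]].residue_name:<4s} {nj:<5s}"
            f"{max(2.0, d + slack):6.2f}"
        )
    # methyl pseudoatom to backbone amide proton
    d = float(
        np.linalg.norm(
            pos[[by[(1, f"HB{k}")] for k in (1, 2, 3)]].mean(axis=0) - pos[by[(3, "H")]]
        )
    )
    lines.append(f"{1:>4d} ALA  QB   {3:>4d} ALA  H    {max(2.0, d - 0.5):6.2f}")
    return "\n".join(lines) + "\n"
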