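"""UFF energies and analytic forces.

Implements the classic rule-based universal force field: harmonic bond
stretch, cosine-Fourier angle bend, periodic torsions, out-of-plane
inversion at sp2 centers and 12-6 Lennard-Jones van der Waals with
geometric combination.  Electrostatics and charge equilibration are
deliberately absent.  All parameters derive from one per-type table
(``data/uff_params.tsv``) through the published combination rules; forces
are the exact negative gradient of the implemented energy.

Exclusions: 1-2 and 1-3 pairs carry no vdW interaction, 1-4 pairs interact
at full strength, and there is no distance cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

from .model import BondGraph
from .perception import TypedSystem

__all__ = [
    "UffAtomParams",
    "UffConfig",
    "EnergyForceReport",
    "ParameterError",
    "load_params",
    "get_params",
    "equilibrium_bond_length",
    "bond_force_constant",
    "UffCalculator",
    "energy_forces",
]

_LAMBDA = 0.1332       # bond-order correction prefactor
_KCAL_PREF = 664.12    # force-constant prefactor, kcal/mol units

_GROUP16 = {"O", "S", "Se", "Te"}


class ParameterError(KeyError):
    """A UFF type or term parameter could not be resolved."""


@dataclass(frozen=True)
class UffAtomParams:
    """Per-type UFF parameters (one row of the parameter table)."""

    label: str
    r1: float       # valence bond radius, A
    theta0: float   # ideal valence angle, deg
    x1: float       # vdW characteristic distance, A
    d1: float       # vdW well depth, kcal/mol
    zeta: float     # vdW shape parameter (unused by the 12-6 form)
    z1: float       # effective charge for force-constant rules
    v_sp3: float    # sp3 torsional barrier, kcal/mol
    u_sp2: float    # sp2 torsional parameter
    chi: float      # GMP electronegativity

    @property
    def element(self) -> str:
        return self.label.rstrip("_0123456789+Rbz_")[:2].strip("_") or self.label[0]

    @property
    def hybridization(self) -> str | None:
        """'3', '2', 'R', '1' when encoded in the label, else None."""
        if len(self.label) >= 3 and self.label[1] == "_":
            return self.label[2] if self.label[2] in "123R" else None
        return None


@lru_cache(maxsize=1)
def load_params() -> dict[str, UffAtomParams]:
    """Load the shipped parameter table, keyed by UFF type label."""
    table: dict[str, UffAtomParams] = {}
    text = resources.files("noemin").joinpath("data/uff_params.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("type\t"):
            continue
        parts = line.split()
        table[parts[0]] = UffAtomParams(
            label=parts[0],
            r1=float(parts[1]), theta0=float(parts[2]), x1=float(parts[3]),
            d1=float(parts[4]), zeta=float(parts[5]), z1=float(parts[6]),
            v_sp3=float(parts[7]), u_sp2=float(parts[8]), chi=float(parts[9]),
        )
    return table


def get_params(label: str) -> UffAtomParams:
    try:
        return load_params()[label]
    except KeyError:
        raise ParameterError(f"unknown UFF type {label!r}") from None


def _element_of(label: str) -> str:
    head = label.split("_")[0].rstrip("0123456789+")
    return head


def equilibrium_bond_length(
    type_i: str, type_j: str, bond_order: float = 1.0,
    override: float | None = None,
) -> float:
    """Natural bond length r_IJ (A): radii sum + bond-order correction
    - electronegativity correction; an override is returned verbatim."""
    if override is not None:
        if override <= 0:
            raise ParameterError(f"bond override {override} must be positive")
        return override
    pi, pj = get_params(type_i), get_params(type_j)
    r_sum = pi.r1 + pj.r1
    r_bo = -_LAMBDA * r_sum * math.log(bond_order)
    chi_i, chi_j = pi.chi, pj.chi
    r_en = (
        pi.r1 * pj.r1 * (math.sqrt(chi_i) - math.sqrt(chi_j)) ** 2
        / (chi_i * pi.r1 + chi_j * pj.r1)
    )
    return r_sum + r_bo - r_en


def bond_force_constant(type_i: str, type_j: str, r_ij: float) -> float:
    """k_IJ = 664.12 Z_I Z_J / r_IJ^3 (kcal/mol/A^2)."""
    pi, pj = get_params(type_i), get_params(type_j)
    return _KCAL_PREF * pi.z1 * pj.z1 / r_ij**3


@dataclass
class UffConfig:
    """Term toggles; inversion can be disabled to match four-term variants."""

    include_bonds: bool = True
    include_angles: bool = True
    include_torsions: bool = True
    include_inversion: bool = True
    include_vdw: bool = True


@dataclass
class EnergyForceReport:
    e_bond: float
    e_angle: float
    e_torsion: float
    e_inversion: float
    e_vdw: float
    e_restraint: float
    forces: np.ndarray

    @property
    def e_total(self) -> float:
        return (
            self.e_bond + self.e_angle + self.e_torsion
            + self.e_inversion + self.e_vdw + self.e_restraint
        )


# ---------------------------------------------------------------------------
# term construction
# ---------------------------------------------------------------------------

@dataclass
class _Terms:
    # bonds
    b_i: np.ndarray
    b_j: np.ndarray
    b_r0: np.ndarray
    b_k: np.ndarray
    # angles: i-j-k with j central
    a_i: np.ndarray
    a_j: np.ndarray
    a_k: np.ndarray
    a_kf: np.ndarray
    a_c0: np.ndarray
    a_c1: np.ndarray
    a_c2: np.ndarray
    a_linear: np.ndarray
    # torsions i-j-k-l
    t_i: np.ndarray
    t_j: np.ndarray
    t_k: np.ndarray
    t_l: np.ndarray
    t_v: np.ndarray      # half-barrier already includes the 1/2 factor
    t_n: np.ndarray
    t_sign: np.ndarray   # cos(n phi0), +-1
    # inversions: center j, wings i,k, out-of-plane l
    v_i: np.ndarray
    v_j: np.ndarray
    v_k: np.ndarray
    v_l: np.ndarray
    v_kf: np.ndarray
    v_c0: np.ndarray
    v_c1: np.ndarray
    v_c2: np.ndarray
    # vdW pairs
    nb_i: np.ndarray
    nb_j: np.ndarray
    nb_x: np.ndarray
    nb_d: np.ndarray


def _bond_equilibrium(system: TypedSystem, i: int, j: int, order: float) -> float:
    override = system.bond_overrides.get((min(i, j), max(i, j)))
    return equilibrium_bond_length(
        system.uff_types[i], system.uff_types[j], order, override=override
    )


def build_terms(system: TypedSystem, config: UffConfig | None = None) -> _Terms:
    config = config or UffConfig()
    types = system.uff_types
    graph = system.bonds
    n = len(types)
    params = [get_params(t) for t in types]

    # ---- bonds ----
    b_i, b_j, b_r0, b_k = [], [], [], []
    r0_cache: dict[tuple[int, int], float] = {}
    for b in graph.bonds:
        r0 = _bond_equilibrium(system, b.i, b.j, b.order)
        r0_cache[(b.i, b.j)] = r0
        b_i.append(b.i)
        b_j.append(b.j)
        b_r0.append(r0)
        b_k.append(bond_force_constant(types[b.i], types[b.j], r0))

    # ---- angles ----
    a_i, a_j, a_k, a_kf, a_c0, a_c1, a_c2, a_lin = [], [], [], [], [], [], [], []
    for j in range(n):
        nbrs = graph.neighbors(j)
        theta0 = math.radians(params[j].theta0)
        cos0, sin0 = math.cos(theta0), math.sin(theta0)
        linear = abs(params[j].theta0 - 180.0) < 1e-6
        for ai_idx in range(len(nbrs)):
            for ak_idx in range(ai_idx + 1, len(nbrs)):
                i, k = nbrs[ai_idx], nbrs[ak_idx]
                rij = r0_cache[(min(i, j), max(i, j))]
                rjk = r0_cache[(min(j, k), max(j, k))]
                rik2 = rij**2 + rjk**2 - 2.0 * rij * rjk * cos0
                kf = (
                    _KCAL_PREF * params[i].z1 * params[k].z1 / rik2**2.5
                    * (3.0 * rij * rjk * sin0**2 - rik2 * cos0)
                )
                if linear:
                    c2, c1, c0 = 0.0, 1.0, 1.0  # E = K (1 + cos theta)
                else:
                    c2 = 1.0 / (4.0 * sin0**2)
                    c1 = -4.0 * c2 * cos0
                    c0 = c2 * (2.0 * cos0**2 + 1.0)
                a_i.append(i); a_j.append(j); a_k.append(k)
                a_kf.append(kf); a_c0.append(c0); a_c1.append(c1); a_c2.append(c2)
                a_lin.append(linear)

    # ---- torsions ----
    t_i, t_j, t_k, t_l, t_v, t_n, t_sign = [], [], [], [], [], [], []
    hyb = [p.hybridization for p in params]
    elem = [_element_of(t) for t in types]
    for b in graph.bonds:
        j, k = b.i, b.j
        term = _torsion_rule(j, k, b.order, hyb, elem, params, graph)
        if term is None:
            continue
        v, n_per, sign = term
        pairs = [
            (i, l)
            for i in graph.neighbors(j) if i != k
            for l in graph.neighbors(k) if l != j and l != i
        ]
        if not pairs:
            continue
        v_each = 0.5 * v / len(pairs)  # half-barrier split over paths
        for i, l in pairs:
            t_i.append(i); t_j.append(j); t_k.append(k); t_l.append(l)
            t_v.append(v_each); t_n.append(n_per); t_sign.append(sign)

    # ---- inversions ----
    v_i, v_j, v_k, v_l, v_kf, v_c0, v_c1, v_c2 = [], [], [], [], [], [], [], []
    if config.include_inversion:
        for j in range(n):
            if types[j] not in ("C_2", "C_R", "N_2", "N_R"):
                continue
            nbrs = graph.neighbors(j)
            if len(nbrs) != 3:
                continue
            kf = 6.0
            if types[j] in ("C_2", "C_R") and any(
                types[nb] == "O_2" and (graph.get_bond(j, nb).order >= 2.0)
                for nb in nbrs
            ):
                kf = 50.0
            kf /= 3.0  # split over the three wing permutations
            for axis in range(3):
                l = nbrs[axis]
                i, k = (x for pos, x in enumerate(nbrs) if pos != axis)
                v_i.append(i); v_j.append(j); v_k.append(k); v_l.append(l)
                v_kf.append(kf); v_c0.append(1.0); v_c1.append(-1.0); v_c2.append(0.0)

    # ---- vdW pairs: all pairs minus 1-2 and 1-3 ----
    excluded: set[tuple[int, int]] = set()
    for b in graph.bonds:
        excluded.add((b.i, b.j))
    for j in range(n):
        nbrs = graph.neighbors(j)
        for ai_idx in range(len(nbrs)):
            for ak_idx in range(ai_idx + 1, len(nbrs)):
                i, k = nbrs[ai_idx], nbrs[ak_idx]
                excluded.add((min(i, k), max(i, k)))
    iu, ju = np.triu_indices(n, k=1)
    if excluded:
        mask = np.array([(a, b_) not in excluded for a, b_ in zip(iu, ju)])
        iu, ju = iu[mask], ju[mask]
    x1 = np.array([p.x1 for p in params])
    d1 = np.array([p.d1 for p in params])
    nb_x = np.sqrt(x1[iu] * x1[ju])
    nb_d = np.sqrt(d1[iu] * d1[ju])

    as_arr = lambda v, dt=float: np.asarray(v, dtype=dt)
    return _Terms(
        b_i=as_arr(b_i, int), b_j=as_arr(b_j, int), b_r0=as_arr(b_r0), b_k=as_arr(b_k),
        a_i=as_arr(a_i, int), a_j=as_arr(a_j, int), a_k=as_arr(a_k, int),
        a_kf=as_arr(a_kf), a_c0=as_arr(a_c0), a_c1=as_arr(a_c1), a_c2=as_arr(a_c2),
        a_linear=as_arr(a_lin, bool),
        t_i=as_arr(t_i, int), t_j=as_arr(t_j, int), t_k=as_arr(t_k, int),
        t_l=as_arr(t_l, int), t_v=as_arr(t_v), t_n=as_arr(t_n), t_sign=as_arr(t_sign),
        v_i=as_arr(v_i, int), v_j=as_arr(v_j, int), v_k=as_arr(v_k, int),
        v_l=as_arr(v_l, int), v_kf=as_arr(v_kf),
        v_c0=as_arr(v_c0), v_c1=as_arr(v_c1), v_c2=as_arr(v_c2),
        nb_i=iu.astype(int), nb_j=ju.astype(int), nb_x=nb_x, nb_d=nb_d,
    )


def _torsion_rule(j, k, order, hyb, elem, params, graph):
    """(barrier V, periodicity n, cos(n phi0)) for the central bond, or None."""
    hj, hk = hyb[j], hyb[k]
    sp3_j, sp3_k = hj == "3", hk == "3"
    sp2_j, sp2_k = hj in ("2", "R"), hk in ("2", "R")

    if sp3_j and sp3_k:
        if elem[j] in _GROUP16 and elem[k] in _GROUP16:
            vj = 2.0 if elem[j] == "O" else 6.8
            vk = 2.0 if elem[k] == "O" else 6.8
            return math.sqrt(vj * vk), 2.0, -1.0  # phi0 = 90
        return math.sqrt(params[j].v_sp3 * params[k].v_sp3), 3.0, -1.0  # phi0 = 60/180
    if sp2_j and sp2_k:
        v = 5.0 * math.sqrt(params[j].u_sp2 * params[k].u_sp2) * (
            1.0 + 4.18 * math.log(max(order, 1.0))
        )
        return v, 2.0, 1.0  # phi0 = 180
    if (sp2_j and sp3_k) or (sp3_j and sp2_k):
        sp3_atom, sp2_atom = (k, j) if sp2_j else (j, k)
        if elem[sp3_atom] in _GROUP16 and elem[sp2_atom] not in _GROUP16:
            v = 5.0 * math.sqrt(params[j].u_sp2 * params[k].u_sp2) * (
                1.0 + 4.18 * math.log(max(order, 1.0))
            )
            return v, 2.0, -1.0  # phi0 = 90
        # propene-like: sp2 partner conjugates onward
        if any(
            hyb[nb] in ("2", "R")
            for nb in graph.neighbors(sp2_atom)
            if nb != sp3_atom
        ):
            return 2.0, 3.0, -1.0
        return 1.0, 6.0, 1.0  # phi0 = 0
    return None


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _eval_bonds(t: _Terms, pos, forces) -> float:
    if len(t.b_i) == 0:
        return 0.0
    d = pos[t.b_i] - pos[t.b_j]
    r = np.linalg.norm(d, axis=1)
    dr = r - t.b_r0
    e = 0.5 * t.b_k * dr**2
    # dE/dr along the bond direction
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (t.b_k * dr / r)[:, None] * d
    f = np.nan_to_num(f)
    np.add.at(forces, t.b_i, -f)
    np.add.at(forces, t.b_j, f)
    return float(e.sum())


def _eval_angles(t: _Terms, pos, forces) -> float:
    if len(t.a_i) == 0:
        return 0.0
    u = pos[t.a_i] - pos[t.a_j]
    v = pos[t.a_k] - pos[t.a_j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    # E = K (C0 + C1 c + C2 (2 c^2 - 1)) covers the linear case via C2 = 0
    e = t.a_kf * (t.a_c0 + t.a_c1 * c + t.a_c2 * (2.0 * c**2 - 1.0))
    dedc = t.a_kf * (t.a_c1 + 4.0 * t.a_c2 * c)
    dc_di = (vh - c[:, None] * uh) / nu[:, None]
    dc_dk = (uh - c[:, None] * vh) / nv[:, None]
    fi = -dedc[:, None] * dc_di
    fk = -dedc[:, None] * dc_dk
    np.add.at(forces, t.a_i, fi)
    np.add.at(forces, t.a_k, fk)
    np.add.at(forces, t.a_j, -(fi + fk))
    return float(e.sum())


def _eval_torsions(t: _Terms, pos, forces) -> float:
    if len(t.t_i) == 0:
        return 0.0
    b1 = pos[t.t_j] - pos[t.t_i]
    b2 = pos[t.t_k] - pos[t.t_j]
    b3 = pos[t.t_l] - pos[t.t_k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    b2n = np.linalg.norm(b2, axis=1)
    ok = (n1sq > 1e-18) & (n2sq > 1e-18) & (b2n > 1e-12)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.where(b2n > 0, b2n, 1.0)
    phi = np.arctan2(y, x)
    e = np.where(ok, t.t_v * (1.0 - t.t_sign * np.cos(t.t_n * phi)), 0.0)
    dedphi = np.where(ok, t.t_v * t.t_sign * t.t_n * np.sin(t.t_n * phi), 0.0)
    inv1 = np.where(ok, 1.0 / np.where(n1sq > 0, n1sq, 1.0), 0.0)
    inv2 = np.where(ok, 1.0 / np.where(n2sq > 0, n2sq, 1.0), 0.0)
    dphi_di = -(b2n * inv1)[:, None] * n1
    dphi_dl = (b2n * inv2)[:, None] * n2
    s12 = np.einsum("ij,ij->i", b1, b2) / np.where(b2n > 0, b2n, 1.0) ** 2
    s32 = np.einsum("ij,ij->i", b3, b2) / np.where(b2n > 0, b2n, 1.0) ** 2
    dphi_dj = -(1.0 + s12)[:, None] * dphi_di + s32[:, None] * dphi_dl
    dphi_dk = -(dphi_di + dphi_dj + dphi_dl)
    g = -dedphi
    np.add.at(forces, t.t_i, g[:, None] * dphi_di)
    np.add.at(forces, t.t_j, g[:, None] * dphi_dj)
    np.add.at(forces, t.t_k, g[:, None] * dphi_dk)
    np.add.at(forces, t.t_l, g[:, None] * dphi_dl)
    return float(e.sum())


def _eval_inversions(t: _Terms, pos, forces) -> float:
    if len(t.v_i) == 0:
        return 0.0
    a = pos[t.v_i] - pos[t.v_j]
    b = pos[t.v_k] - pos[t.v_j]
    l = pos[t.v_l] - pos[t.v_j]
    nvec = np.cross(a, b)
    nn = np.linalg.norm(nvec, axis=1)
    ln = np.linalg.norm(l, axis=1)
    ok = (nn > 1e-12) & (ln > 1e-12)
    nn_s = np.where(ok, nn, 1.0)
    ln_s = np.where(ok, ln, 1.0)
    m = nvec / nn_s[:, None]
    u = l / ln_s[:, None]
    s = np.clip(np.einsum("ij,ij->i", m, u), -1.0, 1.0)  # sin of Wilson angle
    cw = np.sqrt(np.clip(1.0 - s**2, 1e-12, 1.0))
    e = np.where(ok, t.v_kf * (t.v_c0 + t.v_c1 * cw + t.v_c2 * (2.0 * cw**2 - 1.0)), 0.0)
    # dE/ds with cos W = sqrt(1 - s^2)
    deds = np.where(ok, t.v_kf * (-t.v_c1 * s / cw - 4.0 * t.v_c2 * s), 0.0)
    w = (u - s[:, None] * m) / nn_s[:, None]
    ds_di = np.cross(b, w)
    ds_dk = np.cross(w, a)
    ds_dl = (m - s[:, None] * u) / ln_s[:, None]
    fi = -deds[:, None] * ds_di
    fk = -deds[:, None] * ds_dk
    fl = -deds[:, None] * ds_dl
    np.add.at(forces, t.v_i, fi)
    np.add.at(forces, t.v_k, fk)
    np.add.at(forces, t.v_l, fl)
    np.add.at(forces, t.v_j, -(fi + fk + fl))
    return float(e.sum())


def _eval_vdw(t: _Terms, pos, forces) -> float:
    if len(t.nb_i) == 0:
        return 0.0
    d = pos[t.nb_i] - pos[t.nb_j]
    r = np.linalg.norm(d, axis=1)
    r = np.where(r > 1e-9, r, 1e-9)
    s6 = (t.nb_x / r) ** 6
    e = t.nb_d * (s6**2 - 2.0 * s6)
    dedr = -12.0 * t.nb_d * s6 * (s6 - 1.0) / r
    f = (dedr / r)[:, None] * d
    np.add.at(forces, t.nb_i, -f)
    np.add.at(forces, t.nb_j, f)
    return float(e.sum())


class UffCalculator:
    """Reusable evaluator: builds term lists once, evaluates per model."""

    def __init__(self, system: TypedSystem, config: UffConfig | None = None):
        self.system = system
        self.config = config or UffConfig()
        self.terms = build_terms(system, self.config)

    def evaluate(self, positions: np.ndarray) -> EnergyForceReport:
        pos = np.asarray(positions, dtype=float)
        forces = np.zeros_like(pos)
        cfg, t = self.config, self.terms
        with np.errstate(all="ignore"):  # corrupt inputs surface as the check below
            e_bond = _eval_bonds(t, pos, forces) if cfg.include_bonds else 0.0
            e_angle = _eval_angles(t, pos, forces) if cfg.include_angles else 0.0
            e_tors = _eval_torsions(t, pos, forces) if cfg.include_torsions else 0.0
            e_inv = _eval_inversions(t, pos, forces) if cfg.include_inversion else 0.0
            e_vdw = _eval_vdw(t, pos, forces) if cfg.include_vdw else 0.0
        if not np.all(np.isfinite(forces)):
            bad = int(np.argmax(~np.isfinite(forces).all(axis=1)))
            raise FloatingPointError(f"non-finite force on atom index {bad}")
        return EnergyForceReport(
            e_bond=e_bond, e_angle=e_angle, e_torsion=e_tors,
            e_inversion=e_inv, e_vdw=e_vdw, e_restraint=0.0, forces=forces,
        )


def energy_forces(
    system: TypedSystem,
    model_index: int = 0,
    config: UffConfig | None = None,
    restraint_set=None,
    restraint_config=None,
) -> EnergyForceReport:
    """One-shot evaluation for a given model, optionally with restraints."""
    calc = UffCalculator(system, config)
    report = calc.evaluate(system.ensemble.models[model_index].positions)
    if restraint_set is not None and restraint_set.restraints:
        from .restraint_force import total_restraint_term

        e_r, f_r = total_restraint_term(
            system.ensemble.models[model_index].positions,
            restraint_set,
            restraint_config,
        )
        report.e_restraint = e_r
        report.forces = report.forces + f_r
    return report
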