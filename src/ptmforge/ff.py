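"""Force-field parameter derivation for non-standard residues.

Implements the three parameter-derivation routes used when a modified
residue has no standard force-field entry, plus evaluation and file I/O:

* harmonic bond/angle constants from quantum-chemistry Hessians via the
  (modified) Seminario projection, using singular value decomposition of
  the non-symmetric interatomic submatrices;
* multiconformational RESP partial charges from electrostatic-potential
  samples, with the two-stage hyperbolic-restraint recipe and hard group
  constraints;
* cosine-series torsion potentials fitted to dihedral-scan energy
  profiles;
* closed-form evaluation of the harmonic and cosine potentials,
  V_r = 1/2 kb (r - req)^2,  V_theta = 1/2 ktheta (theta - theta_eq)^2,
  V_phi = sum k_phi (1 + cos(n phi - phi_s));
* emission/parsing of GROMACS-dialect residue-topology (.itp) text.

Units at this layer are GROMACS-native: nm, kJ mol^-1, degrees for angles
and phases, rad^-2 for angle force constants.  The bundled parameter set
for S-nitroso-L-cysteine (SNC) ships with the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "BondTerm", "AngleTerm", "TorsionSeries", "TorsionTerm", "ChargeSet",
    "HessianBundle", "ESPSample", "TorsionProfile", "ParameterSet",
    "DegenerateHessianError",
    "seminario_bond", "seminario_angle", "resp_fit", "fit_torsion_series",
    "eval_bond", "eval_angle", "eval_torsion",
    "bundled_snc_parameters", "write_parameter_files", "read_parameter_files",
    "A_TO_NM",
]

A_TO_NM = 0.1


class DegenerateHessianError(ValueError):
    """Interatomic Hessian block is numerically zero."""


@dataclass(frozen=True)
class BondTerm:
    atoms: tuple[str, str]
    req: float            # nm
    kb: float             # kJ mol^-1 nm^-2

    def __post_init__(self) -> None:
        if self.req <= 0 or self.kb < 0:
            raise ValueError("bond term requires req > 0 and kb >= 0")


@dataclass(frozen=True)
class AngleTerm:
    atoms: tuple[str, str, str]
    theta_eq: float       # degrees
    k_theta: float        # kJ mol^-1 rad^-2
    corrected: bool = True  # False when no sibling angle shares the center

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_eq < 180.0 or self.k_theta < 0:
            raise ValueError("angle term requires 0 < theta_eq < 180, k >= 0")


@dataclass(frozen=True)
class TorsionTerm:
    k_phi: float          # kJ mol^-1
    n: int                # multiplicity
    phi_s: float          # phase, degrees

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass(frozen=True)
class TorsionSeries:
    atoms: tuple[str, str, str, str]
    terms: tuple[TorsionTerm, ...]


@dataclass
class ChargeSet:
    """Per-atom partial charges (e) with the declared total formal charge."""

    charges: dict[str, float]
    formal_charge: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.charges.values())
        if abs(total - self.formal_charge) > 1e-6:
            raise ValueError(
                f"charges sum to {total:.6f}, expected {self.formal_charge}")

    def __getitem__(self, atom: str) -> float:
        return self.charges[atom]


@dataclass
class HessianBundle:
    """Second derivatives of the energy at a (near-)equilibrium geometry.

    ``hessian`` is the 3N x 3N matrix in kJ mol^-1 nm^-2; ``positions`` are
    in Angstrom; ``conformer`` labels the backbone conformation.
    """

    conformer: str
    atom_names: list[str]
    positions: np.ndarray          # (N, 3), Angstrom
    hessian: np.ndarray            # (3N, 3N), kJ mol^-1 nm^-2

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.hessian = np.asarray(self.hessian, dtype=float)
        n = len(self.atom_names)
        if self.positions.shape != (n, 3) or self.hessian.shape != (3 * n, 3 * n):
            raise ValueError("inconsistent Hessian bundle shapes")
        scale = max(1.0, float(np.abs(self.hessian).max()))
        if np.abs(self.hessian - self.hessian.T).max() > 1e-6 * scale:
            raise ValueError("Hessian must be symmetric to 1e-6 relative")

    def block(self, i: int, j: int) -> np.ndarray:
        return self.hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3]


@dataclass
class ESPSample:
    """Electrostatic potential sampled on grid points around a conformer.

    Units are self-consistent Coulomb units: potential = q / (distance in
    Angstrom); only ratios enter the fit.
    """

    conformer: str
    atom_names: list[str]
    atom_positions: np.ndarray     # (N, 3), Angstrom
    grid_points: np.ndarray        # (M, 3), Angstrom
    values: np.ndarray             # (M,)

    def __post_init__(self) -> None:
        self.atom_positions = np.asarray(self.atom_positions, dtype=float)
        self.grid_points = np.asarray(self.grid_points, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid_points.shape[0] < 10 * self.atom_positions.shape[0]:
            raise ValueError("need at least 10x more grid points than atoms")

    def design_matrix(self) -> np.ndarray:
        d = np.linalg.norm(self.grid_points[:, None, :]
                           - self.atom_positions[None, :, :], axis=2)
        return 1.0 / d


@dataclass
class TorsionProfile:
    """Dihedral scan: QM reference and MM baseline energies on a phi grid.

    Energies are stored shifted so each profile's minimum is zero; the
    difference (reference - baseline) is the fitting target.
    """

    atoms: tuple[str, str, str, str]
    phi: np.ndarray                # degrees
    reference: np.ndarray          # kJ mol^-1
    baseline: np.ndarray           # kJ mol^-1
    conformer: str = ""

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if not (self.phi.shape == self.reference.shape == self.baseline.shape):
            raise ValueError("misaligned torsion profile grids")
        self.reference = self.reference - self.reference.min()
        if self.baseline.size:
            self.baseline = self.baseline - self.baseline.min()

    @property
    def target(self) -> np.ndarray:
        return self.reference - self.baseline


@dataclass
class ParameterSet:
    residue: str
    charges: ChargeSet
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    torsions: list[TorsionSeries] = field(default_factory=list)
    atom_types: dict[str, str] = field(default_factory=dict)

    def bond(self, a: str, b: str) -> BondTerm:
        for t in self.bonds:
            if t.atoms in ((a, b), (b, a)):
                return t
        raise KeyError(f"no bond term {a}-{b}")

    def angle(self, a: str, b: str, c: str) -> AngleTerm:
        for t in self.angles:
            if t.atoms in ((a, b, c), (c, b, a)):
                return t
        raise KeyError(f"no angle term {a}-{b}-{c}")

    def torsion(self, a: str, b: str, c: str, d: str) -> TorsionSeries:
        for t in self.torsions:
            if t.atoms in ((a, b, c, d), (d, c, b, a)):
                return t
        raise KeyError(f"no torsion series {a}-{b}-{c}-{d}")


# --- Seminario-type force constants --------------------------------------

def _svd_projection(block: np.ndarray, direction: np.ndarray) -> float:
    """Project the singular triples of -H_ij onto a unit direction.

    Returns sum_m sigma_m |l_m . u| |r_m . u| over the singular triples
    (sigma_m, l_m, r_m) — the SVD variant of the Seminario eigenvalue
    projection, which keeps everything real for non-symmetric submatrices.
    By Weyl's inequality the singular values dominate the eigenvalue
    magnitudes, so this generally yields stiffer constants.
    """
    u_vecs, sigma, vt = np.linalg.svd(-block)
    return float(np.sum(sigma * np.abs(u_vecs.T @ direction)
                        * np.abs(vt @ direction)))


def _bond_constant(h: HessianBundle, i: int, j: int) -> tuple[float, float]:
    block = h.block(i, j)
    if np.linalg.norm(block) < 1e-8:
        raise DegenerateHessianError(
            f"interatomic Hessian block ({i},{j}) is numerically zero")
    rij = (h.positions[j] - h.positions[i]) * A_TO_NM
    req = float(np.linalg.norm(rij))
    u = rij / req
    # average the two (identical up to transpose) projection directions
    k = 0.5 * (_svd_projection(block, u) + _svd_projection(h.block(j, i), u))
    return req, k


def seminario_bond(h: HessianBundle | Sequence[HessianBundle],
                   i: int, j: int) -> BondTerm:
    """Harmonic bond term from the interatomic Hessian submatrix.

    With several conformer bundles, req and kb are arithmetic means.
    """
    bundles = [h] if isinstance(h, HessianBundle) else list(h)
    if i == j:
        raise ValueError("bond needs two distinct atoms")
    reqs, ks = zip(*(_bond_constant(b, i, j) for b in bundles))
    names = (bundles[0].atom_names[i], bundles[0].atom_names[j])
    return BondTerm(names, float(np.mean(reqs)), float(np.mean(ks)))


def _angle_geometry(h: HessianBundle, i: int, j: int, k: int):
    r_ij = (h.positions[i] - h.positions[j]) * A_TO_NM
    r_kj = (h.positions[k] - h.positions[j]) * A_TO_NM
    u_ij = r_ij / np.linalg.norm(r_ij)
    u_kj = r_kj / np.linalg.norm(r_kj)
    n = np.cross(u_kj, u_ij)
    norm = np.linalg.norm(n)
    if norm < 1e-8:
        raise ValueError(f"atoms {i},{j},{k} are collinear")
    u_n = n / norm
    u_pa = np.cross(u_n, u_ij)           # perpendicular to ij, in plane
    u_pk = np.cross(u_kj, u_n)           # perpendicular to kj, in plane
    theta = np.rad2deg(np.arccos(np.clip(np.dot(u_ij, u_kj), -1, 1)))
    return u_ij, u_kj, u_pa, u_pk, np.linalg.norm(r_ij), np.linalg.norm(r_kj), theta


def _angle_constant(h: HessianBundle, i: int, j: int, k: int,
                    siblings: Sequence[tuple[int, int, int]]) -> tuple[float, float, bool]:
    u_ij, u_kj, u_pa, u_pk, r1, r2, theta = _angle_geometry(h, i, j, k)
    k_pa = _svd_projection(h.block(i, j), u_pa)
    k_pk = _svd_projection(h.block(k, j), u_pk)
    # Allen-style correction: discount each projected bond constant by the
    # squared overlaps with the perpendicular planes of sibling angles that
    # share the same center and terminal bond.
    corr_a, corr_k = 1.0, 1.0
    corrected = False
    for (si, sj, sk) in siblings:
        if sj != j or (si, sj, sk) == (i, j, k) or (sk, sj, si) == (i, j, k):
            continue
        corrected = True
        s_pa = _angle_geometry(h, si, sj, sk)[2]
        s_pk = _angle_geometry(h, si, sj, sk)[3]
        if si == i:
            corr_a += float(np.dot(u_pa, s_pa) ** 2)
        if sk == i:
            corr_a += float(np.dot(u_pa, s_pk) ** 2)
        if si == k:
            corr_k += float(np.dot(u_pk, s_pa) ** 2)
        if sk == k:
            corr_k += float(np.dot(u_pk, s_pk) ** 2)
    inv_k = 1.0 / (r1 ** 2 * k_pa / corr_a) + 1.0 / (r2 ** 2 * k_pk / corr_k)
    # The two-branch compliance sum measures the bend stiffness in the
    # no-half convention; rescale to V = 1/2 k (theta - theta0)^2.
    return theta, 2.0 / inv_k, corrected


def seminario_angle(h: HessianBundle | Sequence[HessianBundle],
                    i: int, j: int, k: int,
                    siblings: Sequence[tuple[int, int, int]] = ()) -> AngleTerm:
    """Harmonic angle term for i-j-k with the shared-center correction.

    ``siblings`` lists all angle triples of the molecule; only those sharing
    the central atom j and a terminal bond with (i, j, k) contribute the
    geometric correction.  When none do, the plain projection value is
    returned and the term is flagged ``corrected=False``.
    """
    bundles = [h] if isinstance(h, HessianBundle) else list(h)
    results = [_angle_constant(b, i, j, k, siblings) for b in bundles]
    thetas, ks, flags = zip(*results)
    names = tuple(bundles[0].atom_names[x] for x in (i, j, k))
    return AngleTerm(names, float(np.mean(thetas)), float(np.mean(ks)),
                     corrected=any(flags))


# --- RESP charge fitting --------------------------------------------------

def _solve_resp(samples: Sequence[ESPSample],
                groups: Sequence[tuple[Sequence[int], float]],
                equivalences: Sequence[Sequence[int]],
                frozen: dict[int, float],
                restrained: np.ndarray,
                a: float, b: float,
                max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Restrained least squares with hard linear constraints.

    Minimizes sum_k (V_k - A q)^2 + sum_i a (sqrt(q_i^2 + b^2) - b) subject
    to group-total, equivalence and frozen-charge constraints, via the
    standard iterated linear solve of the hyperbolic restraint.
    """
    n = len(samples[0].atom_names)
    ata = np.zeros((n, n))
    atb = np.zeros(n)
    for s in samples:
        A = s.design_matrix()
        ata += A.T @ A
        atb += A.T @ s.values
    cons_rows: list[np.ndarray] = []
    cons_vals: list[float] = []
    for idx, total in groups:
        row = np.zeros(n)
        row[list(idx)] = 1.0
        cons_rows.append(row)
        cons_vals.append(total)
    for eq in equivalences:
        first = eq[0]
        for other in eq[1:]:
            row = np.zeros(n)
            row[first], row[other] = 1.0, -1.0
            cons_rows.append(row)
            cons_vals.append(0.0)
    for idx, val in frozen.items():
        row = np.zeros(n)
        row[idx] = 1.0
        cons_rows.append(row)
        cons_vals.append(val)
    C = np.array(cons_rows) if cons_rows else np.zeros((0, n))
    cvals = np.array(cons_vals)
    if C.shape[0]:
        if np.linalg.matrix_rank(np.hstack([C, cvals[:, None]])) \
                > np.linalg.matrix_rank(C):
            raise ValueError("infeasible charge constraints")
    q = np.zeros(n)
    for _ in range(max_iter):
        rest = np.zeros(n)
        rest[restrained] = a / np.sqrt(q[restrained] ** 2 + b ** 2)
        m = C.shape[0]
        kkt = np.zeros((n + m, n + m))
        kkt[:n, :n] = ata + np.diag(rest)
        kkt[:n, n:] = C.T
        kkt[n:, :n] = C
        rhs = np.concatenate([atb, cvals])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            raise ValueError(
                "rank-deficient RESP design; supply more grid points") from None
        q_new = sol[:n]
        if np.max(np.abs(q_new - q)) < tol:
            q = q_new
            break
        q = q_new
    return q


def resp_fit(samples: Sequence[ESPSample],
             constraints: Sequence[tuple[Sequence[str], float]] = (),
             restraint: float | None = None,
             formal_charge: float = 0.0,
             frozen: dict[str, float] | None = None,
             methyl_equivalences: Sequence[Sequence[str]] = ()) -> ChargeSet:
    """Multiconformational RESP charges.

    All conformers enter with equal weight.  ``constraints`` are hard
    (atom-name group, total-charge) pairs — used to pin capping-group
    charges; ``frozen`` pins single atoms.  With ``restraint=None`` the
    two-stage recipe runs: stage 1 restrains all non-hydrogen atoms with
    a=0.0005, stage 2 refits atoms in ``methyl_equivalences`` (typically
    methyl/methylene protons and carbons) under equivalence with a=0.001.
    With an explicit ``restraint`` a single stage runs at that strength.
    The hyperbolic width is b=0.1 throughout.
    """
    if not samples:
        raise ValueError("need at least one conformer sample")
    names = samples[0].atom_names
    index = {n: i for i, n in enumerate(names)}
    for s in samples[1:]:
        if s.atom_names != names:
            raise ValueError("conformers must share the atom roster")
    heavy = np.array([not n.upper().startswith("H") for n in names])
    groups = [([index[n] for n in g], total) for g, total in constraints]
    groups.append((list(range(len(names))), formal_charge))
    frozen_idx = {index[k]: v for k, v in (frozen or {}).items()}
    b = 0.1
    if restraint is not None:
        q = _solve_resp(samples, groups, [], frozen_idx, heavy, restraint, b)
        return ChargeSet(dict(zip(names, map(float, q))), formal_charge)
    # stage 1: all atoms free, weak restraint on heavy atoms
    q1 = _solve_resp(samples, groups, [], frozen_idx, heavy, 0.0005, b)
    if not methyl_equivalences:
        return ChargeSet(dict(zip(names, map(float, q1))), formal_charge)
    # stage 2: refit equivalenced atoms, freeze the rest at stage-1 values
    eq_idx = [[index[n] for n in eq] for eq in methyl_equivalences]
    in_stage2 = {i for eq in eq_idx for i in eq}
    frozen2 = dict(frozen_idx)
    for i in range(len(names)):
        if i not in in_stage2 and i not in frozen2:
            frozen2[i] = float(q1[i])
    q2 = _solve_resp(samples, groups, eq_idx, frozen2, heavy, 0.001, b)
    return ChargeSet(dict(zip(names, map(float, q2))), formal_charge)


# --- torsion-series fitting ----------------------------------------------

def fit_torsion_series(profiles: Sequence[TorsionProfile],
                       multiplicities: Iterable[int] = (1, 2, 3, 4),
                       ) -> tuple[TorsionSeries, float]:
    """Fit sum_n k_n (1 + cos(n phi - phi_s)) to (reference - baseline).

    Phases are restricted to {0, 180}: the fit is linear in c_n with
    c_n = k_n for phi_s = 0 and c_n = -k_n for phi_s = 180.  All supplied
    conformer profiles are fitted simultaneously; a per-profile additive
    offset absorbs the arbitrary energy zero.  Returns the series and the
    RMS residual (kJ mol^-1).
    """
    if not profiles:
        raise ValueError("need at least one torsion profile")
    mults = sorted(set(int(n) for n in multiplicities))
    if not mults or mults[0] < 1:
        raise ValueError("multiplicities must be positive integers")
    n_prof = len(profiles)
    rows: list[np.ndarray] = []
    targets: list[float] = []
    for p_idx, prof in enumerate(profiles):
        phi = np.deg2rad(prof.phi)
        for g, t in zip(phi, prof.target):
            row = np.zeros(len(mults) + n_prof)
            row[:len(mults)] = np.cos(np.array(mults) * g)
            row[len(mults) + p_idx] = 1.0
            rows.append(row)
            targets.append(t)
    A = np.array(rows)
    y = np.array(targets)
    if A.shape[0] < A.shape[1]:
        raise ValueError("fewer grid points than free parameters")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    c = coef[:len(mults)]
    terms = tuple(TorsionTerm(k_phi=float(abs(cn)), n=n,
                              phi_s=0.0 if cn >= 0 else 180.0)
                  for cn, n in zip(c, mults))
    series = TorsionSeries(profiles[0].atoms, terms)
    resid = A @ coef - y
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return series, rms


# --- closed-form evaluation ----------------------------------------------

def eval_bond(term: BondTerm, r: float) -> float:
    """V = 1/2 kb (r - req)^2, r in nm, result in kJ mol^-1."""
    return 0.5 * term.kb * (r - term.req) ** 2


def eval_angle(term: AngleTerm, theta: float) -> float:
    """V = 1/2 ktheta (theta - theta_eq)^2, theta in degrees."""
    d = np.deg2rad(theta - term.theta_eq)
    return 0.5 * term.k_theta * d ** 2


def eval_torsion(series: TorsionSeries, phi: float) -> float:
    """V = sum k_phi (1 + cos(n phi - phi_s)), phi in degrees."""
    phi_r = np.deg2rad(phi)
    return float(sum(t.k_phi * (1.0 + np.cos(t.n * phi_r - np.deg2rad(t.phi_s)))
                     for t in series.terms))


# --- bundled parameters and file I/O -------------------------------------

def bundled_snc_parameters() -> ParameterSet:
    """The packaged S-nitrosocysteine parameter set (FF99SB-compatible)."""
    text = resources.files("ptmforge.data").joinpath(
        "snc_parameters.csv").read_text()
    charges: dict[str, float] = {}
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    torsion_rows: dict[tuple[str, ...], list[TorsionTerm]] = {}
    atom_types: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, *f = line.split(",")
        if kind == "charge":
            charges[f[0]] = float(f[1])
        elif kind == "bond":
            bonds.append(BondTerm((f[0], f[1]), float(f[2]), float(f[3])))
        elif kind == "angle":
            angles.append(AngleTerm((f[0], f[1], f[2]), float(f[3]),
                                    float(f[4]), corrected=f[5] == "corrected"))
        elif kind == "torsion":
            key = (f[0], f[1], f[2], f[3])
            torsion_rows.setdefault(key, []).append(
                TorsionTerm(k_phi=float(f[5]), n=int(f[6]), phi_s=float(f[4])))
        elif kind == "atomtype":
            atom_types[f[0]] = f[1]
    torsions = [TorsionSeries(k, tuple(v)) for k, v in torsion_rows.items()]
    total = sum(charges.values())
    return ParameterSet("SNC", ChargeSet(charges, formal_charge=total),
                        bonds, angles, torsions, atom_types)


def write_parameter_files(pset: ParameterSet) -> dict[str, str]:
    """Emit GROMACS-itp-dialect text for a residue parameter set.

    Returns {"aminoacids.itp": residue topology, "ffbonded.itp": bonded
    parameters}.  Round-trips exactly through
    :func:`read_parameter_files`.
    """
    for atom in pset.charges.charges:
        if atom not in pset.atom_types:
            raise ValueError(f"no atom type mapped for {atom!r}")
    top = io.StringIO()
    top.write(f"[ {pset.residue} ]\n [ atoms ]\n")
    for name, q in pset.charges.charges.items():
        top.write(f"{name:>6s} {pset.atom_types[name]:>4s} {q:12.6f}\n")
    bonded = io.StringIO()
    if pset.bonds:
        bonded.write("[ bondtypes ]\n")
        for t in pset.bonds:
            bonded.write(f"{t.atoms[0]:>6s} {t.atoms[1]:>6s} 1 "
                         f"{t.req:10.6f} {t.kb:14.4f}\n")
    if pset.angles:
        bonded.write("[ angletypes ]\n")
        for t in pset.angles:
            bonded.write(f"{t.atoms[0]:>6s} {t.atoms[1]:>6s} {t.atoms[2]:>6s} 1 "
                         f"{t.theta_eq:10.4f} {t.k_theta:12.4f} "
                         f"; {'corrected' if t.corrected else 'uncorrected'}\n")
    if any(s.terms for s in pset.torsions):
        bonded.write("[ dihedraltypes ]\n")
        for s in pset.torsions:
            for term in s.terms:
                bonded.write(
                    f"{s.atoms[0]:>6s} {s.atoms[1]:>6s} {s.atoms[2]:>6s} "
                    f"{s.atoms[3]:>6s} 9 {term.phi_s:8.2f} "
                    f"{term.k_phi:12.6f} {term.n:3d}\n")
    return {"aminoacids.itp": top.getvalue(), "ffbonded.itp": bonded.getvalue()}


def read_parameter_files(files: dict[str, str]) -> ParameterSet:
    """Parse text emitted by :func:`write_parameter_files`."""
    residue = ""
    charges: dict[str, float] = {}
    atom_types: dict[str, str] = {}
    section = ""
    for line in files["aminoacids.itp"].splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("["):
            name = line.strip("[] ").strip()
            if name == "atoms":
                section = "atoms"
            else:
                residue = name
                section = ""
            continue
        if section == "atoms":
            name, atype, q = line.split()
            charges[name] = float(q)
            atom_types[name] = atype
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    torsion_rows: dict[tuple[str, ...], list[TorsionTerm]] = {}
    section = ""
    for line in files.get("ffbonded.itp", "").splitlines():
        raw = line.split(";")[0].strip()
        comment = line.split(";", 1)[1].strip() if ";" in line else ""
        if not raw:
            continue
        if raw.startswith("["):
            section = raw.strip("[] ").strip()
            continue
        f = raw.split()
        if section == "bondtypes":
            bonds.append(BondTerm((f[0], f[1]), float(f[3]), float(f[4])))
        elif section == "angletypes":
            angles.append(AngleTerm((f[0], f[1], f[2]), float(f[4]),
                                    float(f[5]),
                                    corrected=comment != "uncorrected"))
        elif section == "dihedraltypes":
            key = tuple(f[:4])
            torsion_rows.setdefault(key, []).append(
                TorsionTerm(k_phi=float(f[6]), n=int(f[7]), phi_s=float(f[5])))
    torsions = [TorsionSeries(k, tuple(v)) for k, v in torsion_rows.items()]
    total = sum(charges.values())
    return ParameterSet(residue, ChargeSet(charges, formal_charge=total),
                        bonds, angles, torsions, atom_types)
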