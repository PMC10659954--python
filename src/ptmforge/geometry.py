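"""Internal-coordinate building (NERF), superposition, dihedrals, bonds, clashes.

Conventions
-----------
* Dihedral sign: IUPAC, cis = 0 deg, right-handed positive; measured values
  are reported in (-180, 180] so the planar trans case is +180.
* NERF frame: the local frame at the last reference atom ``c`` uses the
  b->c direction as first axis and the normal of the (a,b,c) plane as third
  axis, so the planar cis/trans examples are bit-reproducible.
* All lengths in Angstrom at this layer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure import Atom, Protein, Residue

__all__ = [
    "InternalCoordinate",
    "Transform",
    "DegenerateFrameError",
    "nerf_place",
    "measure_internal",
    "dihedral",
    "bond_angle",
    "superpose",
    "rotate_dihedral",
    "detect_bonds",
    "count_clashes",
    "covalent_radius",
    "vdw_radius",
    "CLASH_OVERLAP_TOLERANCE",
]

#: Clash rule: two heavy atoms clash when d < r_vdw_i + r_vdw_j - this (A).
CLASH_OVERLAP_TOLERANCE = 0.6

_COLLINEAR_TOL = 1e-8


class DegenerateFrameError(ValueError):
    """The three reference atoms are (nearly) collinear or coincident."""


@dataclass(frozen=True)
class InternalCoordinate:
    """Bond length (A), bond angle and torsion (degrees) placing one atom."""

    r: float
    theta: float
    phi: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("bond length must be positive")
        if not 0.0 < self.theta < 180.0:
            raise ValueError("bond angle must lie strictly inside (0, 180)")


@dataclass(frozen=True)
class Transform:
    """Proper rigid transform ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper orthogonal")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ np.asarray(self.rotation).T \
            + np.asarray(self.translation)


def _load_radius_table(filename: str) -> dict[str, float]:
    text = resources.files("ptmforge.data").joinpath(filename).read_text()
    table: dict[str, float] = {}
    for row in csv.DictReader(
            (l for l in text.splitlines() if not l.startswith("#"))):
        table[row["element"].capitalize()] = float(row["radius"])
    return table


_COVALENT = _load_radius_table("covalent_radii.csv")
_VDW = _load_radius_table("vdw_radii.csv")


def covalent_radius(element: str) -> float:
    try:
        return _COVALENT[element.capitalize()]
    except KeyError:
        raise KeyError(f"no covalent radius for element {element!r}") from None


def vdw_radius(element: str) -> float:
    try:
        return _VDW[element.capitalize()]
    except KeyError:
        raise KeyError(f"no van der Waals radius for element {element!r}") from None


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateFrameError(f"zero-length {what}")
    return v / n


def nerf_place(a: Sequence[float], b: Sequence[float], c: Sequence[float],
               ic: InternalCoordinate) -> np.ndarray:
    """Place atom d from reference frame (a, b, c) and internal coordinates.

    The returned position satisfies |d-c| = ic.r, angle(b,c,d) = ic.theta and
    dihedral(a,b,c,d) = ic.phi to machine precision.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ab = b - a
    bc = c - b
    u_bc = _unit(bc, "b->c axis")
    n = np.cross(ab, bc)
    if np.linalg.norm(n) < _COLLINEAR_TOL:
        raise DegenerateFrameError("reference atoms a, b, c are collinear")
    n = _unit(n)
    m = np.cross(n, u_bc)
    theta = np.deg2rad(ic.theta)
    phi = np.deg2rad(ic.phi)
    d_local = ic.r * np.array([-np.cos(theta),
                               np.sin(theta) * np.cos(phi),
                               np.sin(theta) * np.sin(phi)])
    return c + d_local[0] * u_bc + d_local[1] * m + d_local[2] * n


def bond_angle(a: Sequence[float], b: Sequence[float], c: Sequence[float]) -> float:
    """Angle a-b-c in degrees."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u = _unit(a - b, "ba bond")
    v = _unit(c - b, "bc bond")
    return float(np.rad2deg(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d in degrees, IUPAC convention, in (-180, 180]."""
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateFrameError("dihedral undefined: collinear atoms")
    u_b2 = _unit(b2, "central bond")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), u_b2))
    angle = np.rad2deg(np.arctan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def measure_internal(a, b, c, d) -> InternalCoordinate:
    """Inverse of :func:`nerf_place`: (r, theta, phi) of d in frame (a,b,c)."""
    c_arr, d_arr = np.asarray(c, dtype=float), np.asarray(d, dtype=float)
    r = float(np.linalg.norm(d_arr - c_arr))
    if r < 1e-12:
        raise ValueError("coincident atoms c and d")
    return InternalCoordinate(r=r, theta=bond_angle(b, c, d),
                              phi=dihedral(a, b, c, d))


def superpose(moving: np.ndarray, reference: np.ndarray) -> tuple[Transform, float]:
    """Least-squares rigid superposition of ``moving`` onto ``reference``.

    Correspondence is by index.  Returns the optimal proper transform and the
    post-fit RMSD in Angstrom.  The rotation is found with the quaternion
    (Kabsch-equivalent) algorithm of scipy's ``Rotation.align_vectors``.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if moving.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    mov_c = moving.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_c, moving - mov_c)
    R = rot.as_matrix()
    t = ref_c - R @ mov_c
    fitted = moving @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return Transform(R, t), rmsd


def rotate_about_axis(points: np.ndarray, origin: Sequence[float],
                      axis: Sequence[float], angle_deg: float) -> np.ndarray:
    """Rotate points right-handedly about an axis through ``origin``."""
    origin = np.asarray(origin, dtype=float)
    u = _unit(np.asarray(axis, dtype=float), "rotation axis")
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * u)
    return rot.apply(np.asarray(points, dtype=float) - origin) + origin


def rotate_dihedral(residue: Residue, axis_atoms: tuple[str, str],
                    angle: float, moving_set: Iterable[str]) -> Residue:
    """Rotate ``moving_set`` atoms about the p->q axis by ``angle`` degrees.

    A positive angle increases any dihedral measured with (p, q) as the
    central bond.  Axis atoms must not be in the moving set; all other atoms
    are untouched.  Returns a new residue.
    """
    moving = list(moving_set)
    p_name, q_name = axis_atoms
    if p_name in moving or q_name in moving:
        raise ValueError("moving set must exclude the axis atoms")
    out = residue.copy()
    p = out.atom(p_name).position
    q = out.atom(q_name).position
    for name in moving:
        atom = out.atom(name)  # raises KeyError if missing
        atom.position = rotate_about_axis(atom.position[None, :], p, q - p,
                                          angle)[0]
    return out


def detect_bonds(atoms: Sequence[Atom]) -> set[tuple[int, int]]:
    """Perceive bonds: (i, j) iff d_ij < 1.2 * (r_cov_i + r_cov_j)."""
    if not atoms:
        return set()
    radii = np.array([covalent_radius(a.element) for a in atoms])
    pos = np.array([a.position for a in atoms])
    dist = cdist(pos, pos)
    cutoff = 1.2 * (radii[:, None] + radii[None, :])
    bonded = (dist < cutoff) & (dist > 1e-6)
    return {(i, j) for i in range(len(atoms)) for j in range(i + 1, len(atoms))
            if bonded[i, j]}


def _is_heavy(atom: Atom) -> bool:
    return atom.element.capitalize() != "H"


def count_clashes(protein: Protein, candidate_atoms: Sequence[Atom],
                  exclusions: Iterable[tuple[Atom, Atom]] = (),
                  exclude_residues: Iterable[Residue] = ()) -> int:
    """Count steric clashes between candidate atoms and the protein.

    A heavy-atom pair clashes when its distance is below
    ``r_vdw_i + r_vdw_j - CLASH_OVERLAP_TOLERANCE``.  Pairs listed in
    ``exclusions`` (compared by object identity) are skipped, as are all
    atoms of residues in ``exclude_residues`` (typically the residue being
    edited and its bonded neighbors).
    """
    excluded_pairs = {frozenset((id(a), id(b))) for a, b in exclusions}
    excluded_atoms = {id(a) for res in exclude_residues for a in res.atoms}
    cand = [a for a in candidate_atoms if _is_heavy(a)]
    env = [a for _, _, a in protein.iter_atoms()
           if _is_heavy(a) and id(a) not in excluded_atoms]
    if not cand or not env:
        return 0
    cand_ids = {id(a) for a in cand}
    env = [a for a in env if id(a) not in cand_ids]
    if not env:
        return 0
    cpos = np.array([a.position for a in cand])
    epos = np.array([a.position for a in env])
    crad = np.array([vdw_radius(a.element) for a in cand])
    erad = np.array([vdw_radius(a.element) for a in env])
    dist = cdist(cpos, epos)
    limit = crad[:, None] + erad[None, :] - CLASH_OVERLAP_TOLERANCE
    clashes = 0
    for i, j in zip(*np.nonzero(dist < limit)):
        if frozenset((id(cand[i]), id(env[j]))) in excluded_pairs:
            continue
        clashes += 1
    return clashes
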