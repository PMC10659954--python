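"""Seeded generators for every synthetic input the toolkit consumes.

These stand in for the quantum-chemistry and molecular-dynamics engines at
desk scale: analytic Hessians of known harmonic force fields, Coulomb
electrostatic potentials of known point charges, exact cosine torsion
profiles, Gaussian-jitter trajectories and Crooks-consistent Gaussian work
samples.  Every generator takes an explicit seed and is bit-reproducible;
no global random state is touched.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import ptm
from .analysis import Trajectory, WorkSamples
from .ff import (ESPSample, HessianBundle, TorsionProfile, TorsionSeries,
                 eval_torsion)
from .geometry import bond_angle, vdw_radius
from .structure import Protein

__all__ = [
    "make_toy_protein", "make_harmonic_hessian", "make_point_charge_esp",
    "make_torsion_profile", "make_jitter_trajectory", "make_gaussian_work",
]

A_TO_NM = 0.1


def make_toy_protein(n_residues: int,
                     sequence: Optional[Sequence[str]] = None,
                     chain: str = "A") -> Protein:
    """Extended-conformation polypeptide built from the template library.

    Backbone torsions default to the beta-strand values; residues are
    numbered consecutively from 1.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    if sequence is None:
        sequence = ["ALA"] * n_residues
    sequence = [s.upper() for s in sequence]
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    protein = Protein()
    protein = ptm.prepend(protein, chain=chain, residue=sequence[0])
    for code in sequence[1:]:
        protein = ptm.append(protein, chain=chain, residue=code)
    return protein


def _bond_gradient(pos_nm: np.ndarray, i: int, j: int) -> np.ndarray:
    grad = np.zeros_like(pos_nm)
    rij = pos_nm[i] - pos_nm[j]
    u = rij / np.linalg.norm(rij)
    grad[i] = u
    grad[j] = -u
    return grad.ravel()


def _angle_gradient(pos_nm: np.ndarray, i: int, j: int, k: int) -> np.ndarray:
    grad = np.zeros_like(pos_nm)
    rji = pos_nm[i] - pos_nm[j]
    rjk = pos_nm[k] - pos_nm[j]
    dji, djk = np.linalg.norm(rji), np.linalg.norm(rjk)
    u, v = rji / dji, rjk / djk
    cos_t = float(np.clip(np.dot(u, v), -1.0, 1.0))
    sin_t = np.sqrt(max(1.0 - cos_t ** 2, 1e-14))
    grad[i] = (cos_t * u - v) / (dji * sin_t)
    grad[k] = (cos_t * v - u) / (djk * sin_t)
    grad[j] = -grad[i] - grad[k]
    return grad.ravel()


def make_harmonic_hessian(atom_names: Sequence[str],
                          positions: np.ndarray,
                          bonds: Sequence[tuple[int, int, float]] = (),
                          angles: Sequence[tuple[int, int, int, float]] = (),
                          conformer: str = "alpha",
                          equilibrium: Optional[dict] = None) -> HessianBundle:
    """Analytic Hessian of a diagonal harmonic force field at equilibrium.

    ``bonds`` are (i, j, kb) with kb in kJ mol^-1 nm^-2 and the current
    distance as the equilibrium length; ``angles`` are (i, j, k, ktheta)
    with j central and ktheta in kJ mol^-1 rad^-2.  At equilibrium the
    exact Hessian is the Gauss-Newton form sum_q k_q (dq/dx)(dq/dx)^T.
    ``equilibrium`` may pin expected values {("bond", i, j): req_nm, ...};
    a geometry off those values is rejected.
    """
    positions = np.asarray(positions, dtype=float)
    pos_nm = positions * A_TO_NM
    n = len(atom_names)
    if equilibrium:
        for key, expected in equilibrium.items():
            if key[0] == "bond":
                actual = float(np.linalg.norm(pos_nm[key[1]] - pos_nm[key[2]]))
            else:
                actual = bond_angle(positions[key[1]], positions[key[2]],
                                    positions[key[3]])
            if abs(actual - expected) > 1e-6:
                raise ValueError(
                    f"geometry is not at the declared equilibrium for {key}")
    h = np.zeros((3 * n, 3 * n))
    for i, j, kb in bonds:
        g = _bond_gradient(pos_nm, i, j)
        h += kb * np.outer(g, g)
    for i, j, k, kt in angles:
        g = _angle_gradient(pos_nm, i, j, k)
        h += kt * np.outer(g, g)
    return HessianBundle(conformer, list(atom_names), positions, h)


def make_point_charge_esp(charges: Sequence[float],
                          positions: np.ndarray,
                          n_points: int,
                          seed: int,
                          elements: Optional[Sequence[str]] = None,
                          conformer: str = "alpha",
                          atom_names: Optional[Sequence[str]] = None,
                          ) -> ESPSample:
    """Coulomb potential of point charges on a random outer shell.

    Grid points are drawn uniformly in a bounding box and kept when they
    lie outside 1.4x the van der Waals surface of every atom, mimicking the
    exclusion zone of standard charge-fitting grids.
    """
    positions = np.asarray(positions, dtype=float)
    n_atoms = positions.shape[0]
    if n_points < 10 * n_atoms:
        raise ValueError("need at least 10x more grid points than atoms")
    if elements is None:
        elements = ["C"] * n_atoms
    if atom_names is None:
        atom_names = [f"X{i+1}" for i in range(n_atoms)]
    radii = 1.4 * np.array([vdw_radius(e) for e in elements])
    rng = np.random.default_rng(seed)
    lo = positions.min(axis=0) - 5.0
    hi = positions.max(axis=0) + 5.0
    points: list[np.ndarray] = []
    while len(points) < n_points:
        cand = rng.uniform(lo, hi, size=(4 * n_points, 3))
        d = np.linalg.norm(cand[:, None, :] - positions[None, :, :], axis=2)
        ok = np.all(d > radii[None, :], axis=1)
        points.extend(cand[ok])
    grid = np.array(points[:n_points])
    d = np.linalg.norm(grid[:, None, :] - positions[None, :, :], axis=2)
    values = (np.asarray(charges, dtype=float)[None, :] / d).sum(axis=1)
    return ESPSample(conformer, list(atom_names), positions, grid, values)


def make_torsion_profile(series: TorsionSeries,
                         grid: Optional[Sequence[float]] = None,
                         conformer: str = "") -> TorsionProfile:
    """Exact evaluation of a cosine series on a phi grid, baseline zero."""
    if grid is None:
        grid = np.arange(-180.0, 180.0, 15.0)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 12:
        raise ValueError("need at least 12 grid points")
    energies = np.array([eval_torsion(series, p) for p in grid])
    return TorsionProfile(series.atoms, grid, energies,
                          np.zeros_like(energies), conformer)


def make_jitter_trajectory(protein: Protein, sigma: float, n_frames: int,
                           seed: int) -> Trajectory:
    """Frames = reference coordinates + iid isotropic Gaussian jitter.

    ``sigma`` is the per-coordinate standard deviation in Angstrom, so the
    expected per-atom RMSF is sqrt(3) * sigma.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    base = np.array([a.position for _, _, a in protein.iter_atoms()])
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(n_frames, *base.shape)) if sigma > 0 \
        else np.zeros((n_frames, *base.shape))
    return Trajectory(base[None, :, :] + noise)


def make_gaussian_work(delta_g: float, sigma2: float, n: int,
                       seed: int, temperature: float = 300.0) -> WorkSamples:
    """Crooks-consistent Gaussian work samples (units of kT).

    Forward work ~ N(dG + sigma^2/2, sigma^2) and backward (reverse
    direction) work ~ N(-dG + sigma^2/2, sigma^2), which satisfy the
    Crooks fluctuation relation exactly, so the Bennett estimator's
    asymptotic answer is ``delta_g`` by construction.
    """
    if n < 1 or sigma2 < 0:
        raise ValueError("need n >= 1 and sigma2 >= 0")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(sigma2)
    forward = rng.normal(delta_g + sigma2 / 2.0, sd, size=n)
    backward = rng.normal(-delta_g + sigma2 / 2.0, sd, size=n)
    return WorkSamples(forward, backward, temperature)
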