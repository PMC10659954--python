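"""Post-simulation statistics: persistent contacts, RMSF, and BAR free energies.

Work and free energies are handled in kT internally (the Bennett equation
is unit-free in kT); helpers convert to kJ mol^-1 at a given temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

from .geometry import superpose
from .structure import Protein, SiteSelector, find_residue, parse_site

__all__ = [
    "Trajectory", "ContactReport", "WorkSamples", "BARResult",
    "close_contacts", "rmsf", "bar_delta_g", "chain_delta_g",
    "CONTACT_DISTANCE_NM", "CONTACT_PERSISTENCE", "kt_to_kj_per_mol",
]

#: Close-contact criteria: any-atom distance below 0.35 nm in at least 70%
#: of the frames, excluding the peptide-bonded neighbors.
CONTACT_DISTANCE_NM = 0.35
CONTACT_PERSISTENCE = 0.70

_BOLTZMANN_KJ = 0.00831446261815324  # kJ mol^-1 K^-1


def kt_to_kj_per_mol(value_kt: float, temperature: float = 300.0) -> float:
    return value_kt * _BOLTZMANN_KJ * temperature


@dataclass
class Trajectory:
    """Coordinate snapshots (Angstrom) for a fixed atom roster."""

    frames: np.ndarray            # (n_frames, n_atoms, 3)
    frame_interval: float = 1.0   # opaque time units

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class ContactReport:
    site: str
    contacts: list[tuple[str, float]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.contacts)


@dataclass
class WorkSamples:
    """Forward (0->1) and backward (1->0) work values, in kT."""

    forward: np.ndarray
    backward: np.ndarray
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=float)
        self.backward = np.asarray(self.backward, dtype=float)
        if self.forward.size == 0 or self.backward.size == 0:
            raise ValueError("both work samples must be non-empty")
        if not (np.all(np.isfinite(self.forward))
                and np.all(np.isfinite(self.backward))):
            raise ValueError("work values must be finite")


@dataclass(frozen=True)
class BARResult:
    delta_g: float                 # kT
    uncertainty: float             # kT, asymptotic standard error
    overlap_warning: bool = False


def close_contacts(traj: Trajectory, protein: Protein,
                   site: Union[str, SiteSelector]) -> ContactReport:
    """Residues persistently close to the site residue.

    A residue qualifies when its minimum interatomic distance to the site
    residue is below 0.35 nm in at least 70% of the frames; the peptide-bond
    neighbors (numbers i-1 and i+1 in the same chain) are excluded.
    """
    if isinstance(site, str):
        site = parse_site(site)
    target = find_residue(protein, site)
    # map the protein's atoms onto trajectory columns, in iteration order
    atom_meta = [(c.id, r.number, r.name) for c, r, _ in protein.iter_atoms()]
    if len(atom_meta) != traj.n_atoms:
        raise ValueError(
            f"trajectory roster has {traj.n_atoms} atoms, protein has "
            f"{len(atom_meta)}")
    target_idx = [i for i, (cid, num, _) in enumerate(atom_meta)
                  if cid == site.chain and num == target.number]
    cutoff_a = CONTACT_DISTANCE_NM * 10.0
    hits: dict[tuple[str, int, str], int] = {}
    for frame in traj.frames:
        tpos = frame[target_idx]
        near: set[tuple[str, int, str]] = set()
        d = cdist(tpos, frame)
        close_cols = np.nonzero((d < cutoff_a).any(axis=0))[0]
        for col in close_cols:
            cid, num, name = atom_meta[col]
            if cid == site.chain and abs(num - target.number) <= 1:
                continue
            near.add((cid, num, name))
        for key in near:
            hits[key] = hits.get(key, 0) + 1
    n = traj.n_frames
    contacts = [(f"{cid}:{name}{num}", cnt / n)
                for (cid, num, name), cnt in sorted(hits.items())
                if cnt / n >= CONTACT_PERSISTENCE]
    return ContactReport(f"{site.chain}:{target.name}{target.number}", contacts)


def rmsf(traj: Trajectory, selection: Optional[Sequence[int]] = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation after superposition.

    Each frame is rigid-body fitted onto the mean structure (single pass:
    fit to the raw mean, re-average, measure), removing overall translation
    and rotation.  Returns fluctuations in the trajectory's length unit.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    frames = traj.frames
    if selection is not None:
        frames = frames[:, list(selection), :]
    mean = frames.mean(axis=0)
    fitted = np.empty_like(frames)
    for k in range(frames.shape[0]):
        transform, _ = superpose(frames[k], mean)
        fitted[k] = transform.apply(frames[k])
    mean = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))


def _fermi(x: np.ndarray) -> np.ndarray:
    # numerically safe 1 / (1 + exp(x))
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out


def bar_delta_g(samples: WorkSamples) -> BARResult:
    """Bennett-acceptance-ratio free-energy difference, in kT.

    Solves the self-consistency equation

        sum_i f(M + W_F_i - dG) = sum_j f(-M + W_B_j + dG),

    with f the Fermi function and M = ln(n_F / n_B), by bracketed root
    finding; the uncertainty is the standard asymptotic variance estimate.
    A warning flag is raised when the forward/backward work distributions
    barely overlap and the variance estimate diverges.
    """
    wf = samples.forward
    wb = samples.backward
    nf, nb = len(wf), len(wb)
    m = np.log(nf / nb)

    def g(dg: float) -> float:
        return float(_fermi(m + wf - dg).sum() - _fermi(-m + wb + dg).sum())

    lo = min(wf.min(), -wb.max()) - 50.0
    hi = max(wf.max(), -wb.min()) + 50.0
    glo, ghi = g(lo), g(hi)
    if glo == 0.0:
        dg = lo
    elif ghi == 0.0:
        dg = hi
    else:
        dg = brentq(g, lo, hi, xtol=1e-10)
    # asymptotic variance (all-sample Fermi overlap form)
    x = np.concatenate([m + wf - dg, -(-m + wb + dg)])
    weight = 1.0 / (2.0 + 2.0 * np.cosh(np.clip(x, -500, 500)))
    denom = weight.sum()
    overlap_warning = False
    if denom <= 0 or not np.isfinite(denom):
        variance = np.inf
        overlap_warning = True
    else:
        variance = 1.0 / denom - (nf + nb) / (nf * nb)
        if variance <= 0 or not np.isfinite(variance):
            variance = abs(variance)
            overlap_warning = True
        elif variance > 100.0:   # > 10 kT standard error: no usable overlap
            overlap_warning = True
    return BARResult(float(dg), float(np.sqrt(variance)), overlap_warning)


def chain_delta_g(per_leg: Sequence[float],
                  schedule=None) -> tuple[float, dict[str, float]]:
    """Total free-energy change over an ordered sequence of legs.

    With a :class:`~ptmforge.workflow.TISchedule` supplied, the leg count is
    validated against the schedule and per-stage subtotals are keyed by the
    stage labels; otherwise everything lands in one ``"total"`` stage.
    """
    values = [float(x) for x in per_leg]
    subtotals: dict[str, float] = {}
    if schedule is not None:
        if len(values) != len(schedule.legs):
            raise ValueError(
                f"{len(values)} leg values but schedule has "
                f"{len(schedule.legs)} legs")
        for (label, _), v in zip(schedule.legs, values):
            subtotals[label] = subtotals.get(label, 0.0) + v
    else:
        subtotals["total"] = sum(values)
    return float(sum(values)), subtotals
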