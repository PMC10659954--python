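"""Deterministic generation of external-engine input artifacts.

Everything here is pure text generation: quantum-chemistry input decks, MD
equilibration protocols, alchemical lambda schedules, torsion-fit
configurations, docking configurations and batch scripts.  No external
engine is ever invoked; identical inputs always produce byte-identical
text.  Every numeric default lives in :data:`DEFAULTS` so downstream code
(and tests) read each constant from exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .solvation import box_volume, protein_volume, sltcap_ion_counts
from .structure import Protein

__all__ = [
    "DEFAULTS", "TISchedule", "MDProtocol", "QMDeckSet", "DockingConfig",
    "gen_ti_schedule", "gen_equilibration_protocol", "gen_qm_decks",
    "gen_torsion_fit_config", "gen_docking_config", "gen_batch_script",
]

#: Single source of truth for every generator default.
DEFAULTS: dict = {
    # two-stage decoupling: electrostatics first, then vdW + bonded terms
    "ti_lambdas": (0.00, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50,
                   0.60, 0.70, 0.80, 0.90, 0.95, 1.00),
    "ti_stage_labels": ("electrostatic", "vdw-bonded"),
    "ti_leg_duration_ns": 1.0,
    # equilibration
    "box_type": "dodecahedron",
    "box_buffer_nm": 1.0,
    "minimization_ladder": (1000.0, 500.0, 200.0, 100.0, 10.0, 5.0, 1.0),
    "nvt_ps": 500.0,
    "temperature_K": 300.0,
    "npt_unrestrained_ns": 20.0,
    "timestep_fs": 2.0,
    "salt_mol_per_L": 0.15,
    "protein_charge": 0,
    # long preset mirroring the published case study
    "case_study_npt_ns": 500.0,
    "case_study_production_ns": 100.0,
    # QM theory annotations
    "qm_functional": "r2SCAN-D3(BJ)",
    "qm_orbital_basis": "def2-TZVP",
    "qm_jfit_basis": "def2-universal-jfit",
    "qm_grid": "lebedev 120 41",
    "esp_theory": "HF",
    "esp_basis": "6-31G*",
    "scan_basis": "def2-SVP",
    "conformers": (("alpha", -60.0, -45.0), ("beta", -135.0, 135.0)),
    # torsion-fit restraints
    "dihedral_restraint_kj_mol_rad2": 14000.0,
    "position_restraint_kj_mol_nm2": 418.0,
    # docking
    "exhaustiveness": 64,
    "scoring": "vina",
    "min_multi_ligand_box": (19.0, 27.0, 16.0),
    # batch scripts
    "scheduler": "slurm",
    "partition": "normal",
    "walltime": "12:00:00",
    "nodes": 1,
}


@dataclass(frozen=True)
class TISchedule:
    """Two-stage alchemical decoupling plan.

    ``stages`` maps labels to ascending lambda lists in [0, 1]; the fully
    coupled boundary state between consecutive stages is shared, so the
    flattened ``legs`` list has sum(sizes) - (n_stages - 1) entries.
    """

    stages: tuple[tuple[str, tuple[float, ...]], ...]
    legs: tuple[tuple[str, float], ...]
    leg_duration_ns: float


@dataclass(frozen=True)
class MDProtocol:
    box_type: str
    box_buffer_nm: float
    minimization_ladder: tuple[float, ...]
    nvt_ps: float
    temperature_K: float
    npt_ns: float
    timestep_fs: float
    n_cations: int
    n_anions: int


@dataclass(frozen=True)
class QMDeckSet:
    residue: str
    conformers: tuple[tuple[str, float, float], ...]
    geometry_decks: dict[str, str]
    hessian_decks: dict[str, str]
    esp_decks: dict[str, str]
    scan_decks: dict[str, str]


@dataclass(frozen=True)
class DockingConfig:
    receptor: str
    ligands: tuple[str, ...]
    center: tuple[float, float, float]
    size: tuple[float, float, float]
    exhaustiveness: int
    scoring: str
    multi_ligand: bool


def _check_lambdas(lams: Sequence[float]) -> tuple[float, ...]:
    lams = tuple(float(x) for x in lams)
    if list(lams) != sorted(set(lams)):
        raise ValueError("lambda list must be strictly ascending")
    if lams[0] != 0.0 or lams[-1] != 1.0:
        raise ValueError("lambda list must start at 0.00 and end at 1.00")
    return lams


def gen_ti_schedule(stage_lambdas: Optional[dict[str, Sequence[float]]] = None,
                    leg_duration_ns: Optional[float] = None) -> TISchedule:
    """Lambda schedule for the stepwise alchemical transformation.

    The default decouples electrostatics first and then van der Waals plus
    bonded terms, each over the same 13-value lambda list, sharing the fully
    coupled boundary state: 25 one-nanosecond legs in total.
    """
    if stage_lambdas is None:
        lams = DEFAULTS["ti_lambdas"]
        stage_lambdas = {label: lams for label in DEFAULTS["ti_stage_labels"]}
    stages = tuple((label, _check_lambdas(ls))
                   for label, ls in stage_lambdas.items())
    legs: list[tuple[str, float]] = []
    for idx, (label, lams) in enumerate(stages):
        start = 1 if idx > 0 else 0   # shared boundary state
        legs.extend((label, lam) for lam in lams[start:])
    return TISchedule(stages, tuple(legs),
                      leg_duration_ns if leg_duration_ns is not None
                      else DEFAULTS["ti_leg_duration_ns"])


def gen_equilibration_protocol(protein: Protein,
                               **overrides) -> tuple[MDProtocol, str]:
    """Equilibration plan and the corresponding engine-command script text.

    Solvation in a periodic box, charge neutralization with SLTCAP ion
    counts (protein volume excluded from the water volume), an energy
    minimization ladder with stepwise-released restraints, restrained NVT
    thermalization and an unrestrained NPT stage.  The script is text only
    and is never executed by this package.
    """
    cfg = dict(DEFAULTS)
    unknown = set(overrides) - set(cfg)
    if unknown:
        raise ValueError(f"unknown protocol options: {sorted(unknown)}")
    cfg.update(overrides)
    ladder = tuple(float(x) for x in cfg["minimization_ladder"])
    if list(ladder) != sorted(ladder, reverse=True) or len(set(ladder)) != len(ladder):
        raise ValueError("minimization ladder must be strictly decreasing")
    if cfg["nvt_ps"] <= 0 or cfg["npt_unrestrained_ns"] <= 0 or cfg["timestep_fs"] <= 0:
        raise ValueError("durations and timestep must be positive")
    # estimate box and water volume from the protein extent
    coords = [a.position for _, _, a in protein.iter_atoms()]
    if coords:
        import numpy as np
        arr = np.asarray(coords)
        extent_nm = float((arr.max(axis=0) - arr.min(axis=0)).max()) * 0.1
    else:
        extent_nm = 0.0
    image = extent_nm + 2.0 * cfg["box_buffer_nm"]
    v_box = box_volume(image, cfg["box_type"])
    v_protein = protein_volume(protein) if coords else 0.0
    v_water = max(v_box - v_protein, 1e-6)
    plan = sltcap_ion_counts(cfg["protein_charge"], cfg["salt_mol_per_L"],
                             v_water)
    protocol = MDProtocol(cfg["box_type"], cfg["box_buffer_nm"], ladder,
                          cfg["nvt_ps"], cfg["temperature_K"],
                          cfg["npt_unrestrained_ns"], cfg["timestep_fs"],
                          plan.n_cations, plan.n_anions)
    lines = [
        "# equilibration protocol (generated; text only, never executed here)",
        f"editconf -bt {cfg['box_type']} -d {cfg['box_buffer_nm']:g}",
        "solvate -cs spc216",
        f"genion -np {plan.n_cations} -nn {plan.n_anions}"
        f"  # SLTCAP at {cfg['salt_mol_per_L']:g} mol/L,"
        f" water volume {v_water:.1f} nm^3",
    ]
    for k in ladder:
        lines.append(f"mdrun -deffnm min_posre_{k:g}  # restraint {k:g} kJ/mol/nm^2")
    lines.append(f"mdrun -deffnm nvt  # {cfg['nvt_ps']:g} ps at {cfg['temperature_K']:g} K")
    lines.append(f"mdrun -deffnm npt  # {cfg['npt_unrestrained_ns']:g} ns unrestrained NPT,"
                 f" dt {cfg['timestep_fs']:g} fs")
    return protocol, "\n".join(lines) + "\n"


def gen_qm_decks(residue_code: str) -> QMDeckSet:
    """Quantum-chemistry input decks for the capped-dipeptide conformers.

    Geometry optimization and Hessian decks annotate the meta-GGA setup;
    the electrostatic-potential deck annotates the Hartree-Fock/6-31G*
    charge-derivation setup with capping-group charge constraints; the
    torsion-scan deck freezes phi, psi and the scanned dihedral.
    """
    from .ptm import get_template
    get_template(residue_code)  # raises KeyError for unknown residues
    cfg = DEFAULTS
    geometry, hessian, esp, scan = {}, {}, {}, {}
    for label, phi, psi in cfg["conformers"]:
        head = (f"# ACE-{residue_code}-NME dipeptide, {label} conformer"
                f" (phi={phi:g}, psi={psi:g}; both frozen)\n")
        theory = (f"xc {cfg['qm_functional']}\nbasis {cfg['qm_orbital_basis']}\n"
                  f"jfit {cfg['qm_jfit_basis']}\ngrid {cfg['qm_grid']}\n")
        freeze = f"freeze dihedral phi {phi:g}\nfreeze dihedral psi {psi:g}\n"
        geometry[label] = head + "task optimize\n" + theory + freeze
        hessian[label] = head + "task hessian\n" + theory + freeze
        esp[label] = (head + "task esp\n"
                      f"theory {cfg['esp_theory']}\nbasis {cfg['esp_basis']}\n"
                      "grid chelpg\n"
                      "constrain group ACE charge 0.0\n"
                      "constrain group NME charge 0.0\n")
        scan[label] = (head + "task scan\n"
                       f"xc {cfg['qm_functional']}\nbasis {cfg['scan_basis']}\n"
                       + freeze + "freeze dihedral scanned\n")
    return QMDeckSet(residue_code, cfg["conformers"], geometry, hessian,
                     esp, scan)


def gen_torsion_fit_config(profiles: Sequence, *,
                           dihedral_restraint: Optional[float] = None,
                           position_restraint: Optional[float] = None) -> str:
    """Configuration text for the torsion-potential refinement step.

    The scanned dihedral plus the two backbone torsions are restrained
    stiffly; all other atom positions are weakly restrained so orthogonal
    degrees of freedom can relax without drifting from the scan geometry.
    """
    if not profiles:
        raise ValueError("need at least one torsion profile")
    dih = DEFAULTS["dihedral_restraint_kj_mol_rad2"] \
        if dihedral_restraint is None else float(dihedral_restraint)
    pos = DEFAULTS["position_restraint_kj_mol_nm2"] \
        if position_restraint is None else float(position_restraint)
    lines = ["[ torsion-fit ]",
             f"dihedral_restraint {dih:g}  ; kJ mol^-1 rad^-2",
             f"position_restraint {pos:g}  ; kJ mol^-1 nm^-2"]
    for p in profiles:
        atoms = "-".join(p.atoms)
        lines.append(f"profile {atoms} {p.conformer or 'default'} "
                     f"{len(p.phi)} points")
    return "\n".join(lines) + "\n"


def gen_docking_config(receptor: str, ligands: Sequence[str],
                       box: Optional[tuple[tuple[float, float, float],
                                           tuple[float, float, float]]] = None,
                       annotated_site: Optional[tuple[float, float, float]] = None,
                       **overrides) -> tuple[DockingConfig, str]:
    """Docking search configuration (center/size in Angstrom).

    ``box`` is (center, lengths).  Without a box, an annotated binding site
    must provide the center.  With two or more ligands the multi-ligand
    strategy is flagged and box lengths are clamped up to the minimum that
    accommodates both ligands.
    """
    cfg = dict(DEFAULTS)
    cfg.update(overrides)
    if box is None:
        if annotated_site is None:
            raise ValueError(
                "no search box given and the receptor has no annotated "
                "binding site; supply box center and size")
        center = tuple(float(x) for x in annotated_site)
        size = cfg["min_multi_ligand_box"]
    else:
        center = tuple(float(x) for x in box[0])
        size = tuple(float(x) for x in box[1])
    if any(s <= 0 for s in size):
        raise ValueError("box lengths must be positive")
    multi = len(ligands) >= 2
    if multi:
        size = tuple(max(s, m) for s, m in
                     zip(size, cfg["min_multi_ligand_box"]))
    config = DockingConfig(receptor, tuple(ligands), center, size,
                           int(cfg["exhaustiveness"]), cfg["scoring"], multi)
    lines = [f"receptor = {receptor}"]
    lines += [f"ligand = {l}" for l in ligands]
    lines += [f"center_x = {center[0]:g}", f"center_y = {center[1]:g}",
              f"center_z = {center[2]:g}",
              f"size_x = {size[0]:g}", f"size_y = {size[1]:g}",
              f"size_z = {size[2]:g}",
              f"exhaustiveness = {config.exhaustiveness}",
              f"scoring = {config.scoring}"]
    if multi:
        lines.append("# multi-ligand docking mode")
    return config, "\n".join(lines) + "\n"


def gen_batch_script(body: str, **overrides) -> str:
    """Wrap generated commands in a portable scheduler batch script.

    All directives are overridable keyword by keyword; output is
    deterministic for fixed inputs.
    """
    cfg = dict(DEFAULTS)
    cfg.update(overrides)
    lines = ["#!/bin/bash"]
    if cfg["scheduler"] == "slurm":
        lines += [f"#SBATCH --partition={cfg['partition']}",
                  f"#SBATCH --time={cfg['walltime']}",
                  f"#SBATCH --nodes={cfg['nodes']}"]
    lines += ["set -euo pipefail", "", body.rstrip("\n"), ""]
    return "\n".join(lines)
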