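# ptmforge

Post-translational modifications (PTMs) — and redox PTMs of cysteine thiols
in particular, such as S-nitrosylation — regulate protein function, but the
modified residues are absent from standard biomolecular force fields, and
placing them into a structure by hand is error-prone. `ptmforge` is a
Python library for computational structural biologists that covers the desk
work of a PTM simulation study end to end:

* **Structure editing** — read/write PDB, address residues as `"A:CYS155"`,
  mutate residues or apply named chemical reactions (`nitrosylation`,
  `phosphorylation`, ...) from a registry of modifications, cap termini
  with ACE/NME, and build capped dipeptides. New atoms are placed with the
  Natural Extension of Reference Frame (NERF) algorithm from
  internal-coordinate templates; side chains are settled by a chi1/chi2
  rotamer scan in 30° increments that stops at the first clash-free
  combination (or keeps the least-clashing one, with a warning).
* **Force-field parameterization** for non-standard residues from
  quantum-chemistry data:
  * harmonic bond/angle constants by the modified Seminario method — the
    interatomic 3×3 Hessian blocks −∂²E/∂r_i∂r_j are decomposed by SVD
    (avoiding complex eigenvalues of the non-symmetric blocks) and
    projected onto the bond vector, with the shared-central-atom geometric
    correction for angle stiffness;
  * multiconformational RESP charges: least squares on the electrostatic
    potential across conformers with the two-stage hyperbolic restraint
    recipe and hard capping-group constraints;
  * torsion potentials V(φ) = Σ k_φ (1 + cos(nφ − φ_s)) fitted to
    dihedral-scan energy profiles;
  * emission and parsing of GROMACS-dialect `.itp` parameter text, and a
    bundled, literature-consistent parameter set for S-nitroso-L-cysteine
    (SNC).
* **Simulation planning** — SLTCAP ion counts N± = N₀(√(1+t²) ∓ t),
  t = Q/2N₀, computed on the water volume only (protein volume excluded via
  bundled per-residue volumes); equilibration protocols with a decreasing
  restraint ladder; a two-stage alchemical λ schedule (electrostatics, then
  vdW/bonded; 13 λ values per stage sharing the coupled endpoint — 25 legs);
  QM input decks, docking configurations and batch scripts, all as
  deterministic text.
* **Analysis** — persistent close contacts (< 0.35 nm in ≥ 70 % of frames,
  peptide-bonded neighbors excluded), RMSF after optimal superposition, and
  free energies from forward/backward work samples by Bennett's acceptance
  ratio (BAR), solving
  Σ_i f(M + W_F,i − ΔG) = Σ_j f(−M + W_B,j + ΔG), f(x) = 1/(1+eˣ),
  with the standard asymptotic uncertainty.

A `fixtures` module generates every input synthetically (analytic harmonic
Hessians, Coulomb ESP grids, exact torsion profiles, Gaussian-jitter
trajectories, Crooks-consistent Gaussian work), so the whole package is
testable offline with known ground truth. No external QM/MD/docking engine
is ever executed; their input files are generated as text only.

## Worked example

```python
from ptmforge import modify, build_dipeptide
from ptmforge.fixtures import make_toy_protein
from ptmforge.ff import bundled_snc_parameters, eval_torsion

protein = make_toy_protein(3, ["GLY", "CYS", "GLY"])
modified = modify(protein, "A:CYS2", "nitrosylation")
print(modified.chain("A").residues[1].name)   # SNC

snc = bundled_snc_parameters()
print(snc.charges["SG"])                      # -0.1959 (e)
print(snc.bond("SG", "ND").req)               # 0.1918 (nm)
series = snc.torsion("CB", "SG", "ND", "OE")
print(eval_torsion(series, 0.0))              # 2.1538 (kJ/mol at phi = 0)
```

The modified residue keeps every original heavy atom and gains the S-nitroso
N and O; the printed charge, equilibrium bond length and torsion energy come
from the bundled SNC parameter set (the torsion value at φ = 0 is the 1-fold
term's 2·k_φ = 2.1538 kJ/mol, since the 2-, 3- and 4-fold terms vanish at
their 180° phases).

The `examples/` directory holds one short narrative script per capability
(structure editing, parameter derivation, simulation planning, analysis);
each prints the numbers it computes alongside the value they should match.

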