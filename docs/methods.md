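# Methods

This note records the models, conventions and design choices behind
`ptmforge`, in the order a study would use them.

## Structure model and PDB I/O

Coordinates are stored in Angstrom (PDB native) everywhere inside the
structure layer; conversion to nm happens once, at the force-field/
simulation-planning boundary. Residue numbering is taken verbatim from the
input file and never rewritten (prepending a residue before residue 1
yields residue 0, which PDB permits). Alternate locations collapse at parse
time to the highest-occupancy copy, ties broken by file order. Site strings
follow the `chain:RESnumber` syntax (`"A:CYS155"`, or `"A:155"` with the
name omitted); a wrong residue name at an existing position raises a
mismatch error distinct from not-found, because silently editing the wrong
residue is the costliest failure mode of batch PTM studies.

The PDB reader/writer is deliberately minimal and fixed-column, with parse
errors that name the offending line; the test suite cross-checks the
emitted text through gemmi. mmCIF and network fetching are out of scope.

## Geometry

* **Dihedral convention**: IUPAC, cis = 0°, right-handed positive.
  Measured values are reported in (−180°, 180°], so a planar trans
  arrangement is +180°.
* **NERF frame**: an atom d placed on reference triple (a, b, c) uses the
  b→c direction as first axis and the (a,b,c) plane normal as third axis.
  Build and measurement are mutually inverse to < 1e-6 over random frames
  (property-tested). Reference triples within 1e-8 of collinearity are
  rejected rather than guessed around.
* **Superposition** uses the quaternion-based least-squares alignment
  (scipy's `Rotation.align_vectors`), returning the proper rigid transform
  and the post-fit RMSD.
* **Bond perception**: atoms bond when their distance is below 120 % of
  the sum of their covalent radii; the bundled radius table is the Cordero
  single-bond set. At the SNC equilibrium geometries this classifies
  CB—SG (1.803 Å < 2.172 Å) and SG—ND (1.918 Å < 2.112 Å) as bonded.
* **Clash rule**: two heavy atoms clash when d < r_vdw,i + r_vdw,j − 0.6 Å
  (Bondi radii). The 0.6 Å overlap allowance is the common
  visualization-tool default; it is a single module constant
  (`CLASH_OVERLAP_TOLERANCE`). Hydrogens are ignored: the package edits
  heavy-atom structures and delegates protonation to external tools.

## Residue templates and editing

Templates are text files (one per residue, schema documented in each
file) carrying an ordered internal-coordinate build recipe per heavy atom,
backbone-role mapping, and chi1/chi2 atom quadruples. Geometry derives
from Chemical Component Dictionary ideal coordinates; the S-nitroso moiety
of SNC instead carries the equilibrium values of the bundled parameter set
(CB—SG 1.803 Å at CA—CB—SG 113.8°, SG—ND 1.918 Å at CB—SG—ND 99.5°,
ND—OE 1.170 Å at SG—ND—OE 117.2°, φ(CB—SG—ND—OE) = 180°, the minimum of
its 2-fold-dominated torsion potential). Phospho-arginine and
phospho-lysine have no commonly used component codes; their templates
(`RGP`, `KZP`) are synthetic extensions of the parent residues and say so
in their headers.

* **mutate** keeps the backbone atoms (N, CA, C, O) of the edited residue
  bit-identical, superposes the template on (N, CA, C), rotates the new
  side chain about CA to align the β-carbon direction with the original,
  then runs the clash scan. Atoms of every other residue are untouched.
* **modify** keeps all existing heavy atoms, removes hydrogens (the
  product must be re-protonated anyway), places the product template's
  additional atoms by NERF in recipe order, and renames the residue to the
  product code. The registry of (residue, reaction) pairs is tabulated
  data; `carbamoylation`, `nitrosation` and the `dimethylation` spellings
  are accepted as aliases of the tabulated names. Side-chain O-acetylation
  of serine is supported as a documented extra beyond the tabulated
  registry. N-terminal acetylation is reachable only through `prepend`
  (ACE), never through `modify`, to keep it distinct from side-chain
  acetylations.
* **Rotamer scan**: chi1 outer loop, chi2 inner, both starting at the
  template value and stepping +30° (12 values each, 144 combinations);
  the first clash-free combination wins; otherwise the least-clashing one
  (first in lexicographic scan order) is kept and a `ClashWarning` is
  issued. The moving set for each torsion is derived from the residue's
  perceived bond graph (atoms reachable from the distal axis atom), so
  branched side chains rotate correctly.
* **Chain growth** uses trans-amide geometry (ω = 180°, C—N 1.329 Å) and
  defaults to the extended β-strand conformation (φ, ψ = −135°, 135°);
  the α-helical alternative is (−60°, −45°). `build_dipeptide` produces
  the ACE-XXX-NME construct with either pair frozen — the standard
  parameterization geometry.

## Force-field parameterization

Units at this layer are GROMACS-native: nm, kJ mol⁻¹, kJ mol⁻¹ nm⁻² for
bonds, kJ mol⁻¹ rad⁻² for angles, degrees for angles and phases. The
potential conventions are V_r = ½k_b(r−r_eq)², V_θ = ½k_θ(θ−θ_eq)²,
V_φ = Σ k_φ(1 + cos(nφ − φ_s)).

* **Seminario bonds**: k_b = Σ_m σ_m |l_m·û||r_m·û| over the singular
  triples of −∂²E/∂r_i∂r_j, û the unit bond vector, averaged over the
  (i,j)/(j,i) blocks. The SVD keeps the arithmetic real for non-symmetric
  blocks; by Weyl's inequality the singular values dominate eigenvalue
  magnitudes, so constants lean stiff. On analytic Hessians of harmonic
  bonds the input constant is recovered exactly.
* **Seminario angles**: each terminal bond contributes a projected
  constant k_P onto the in-plane perpendicular; the two contributions
  combine as compliances, 1/k = 1/(R₁²k_PA) + 1/(R₂²k_PC). This compliance
  sum measures the bend in the no-half convention, so the result is
  rescaled by 2 to the ½k(θ−θ₀)² convention used throughout. For angles
  sharing the central atom *and* a terminal bond, the projected constants
  are discounted by 1 + Σ cos² of the angles between the sibling
  perpendicular planes; angles with no sibling keep the plain value and
  are flagged `corrected=False` — these are the ones the method is known
  to overestimate. At a 90° bend the projection cross-term vanishes, so
  the right-angle triatomic is the clean identification geometry used by
  the recovery oracles; off-perpendicular single angles are overestimated
  by up to ~25 % — a documented property of the method, not a bug.
* **Conformer handling**: with both α and β Hessians supplied, constants
  and equilibrium values are arithmetic means of the per-conformer derived
  values (order-independent); matrices themselves are never averaged.
* **RESP**: minimize Σ_conformers Σ_k (V_k − Σ_i q_i/r_ik)² with equal
  conformer weights, plus the hyperbolic restraint a(√(q²+b²)−b) on
  non-hydrogen atoms, under hard linear constraints (total charge, group
  totals such as pinned ACE/NME caps, frozen atoms, equivalences). The
  nonlinear restraint is solved by the standard iterated linear KKT
  system. The two-stage recipe uses a = 0.0005 (stage 1, all atoms free)
  and a = 0.001 with methyl/methylene equivalence and all other atoms
  frozen (stage 2); b = 0.1 throughout. With restraint → 0 and exact
  Coulomb data, generating charges are recovered to better than 1e-4 and
  the total-charge constraint holds to machine precision.
* **Torsion fitting** is linear: with phases restricted to {0°, 180°},
  Σ k_n(1+cos(nφ−φ_s)) = const + Σ c_n cos(nφ) with k_n = |c_n| and the
  phase given by the sign of c_n. All supplied conformer profiles are fit
  simultaneously with per-profile offsets absorbing the arbitrary energy
  zeros. The stiff orthogonal-relaxation restraints that accompany a real
  refit (≥ 14 000 kJ mol⁻¹ rad⁻² on the three fixed dihedrals,
  418 kJ mol⁻¹ nm⁻² on positions) belong to the generated fitting
  configuration text — no MD engine runs here, so they are emitted
  constants, not fitting terms.
* The bundled SNC parameter set (charges, three bonds, four angle terms,
  three torsion series, atom-type map) ships as a CSV data file; the
  `.itp` writer/parser round-trips it exactly.

## Solvation and ion counts

SLTCAP with monovalent salt: N₀ = c₀·N_A·V_water, t = Q/2N₀,
N± = N₀(√(1+t²) ∓ t). The closed form satisfies N₊ − N₋ = −Q exactly and
N₊·N₋ = N₀² (asserted to 1e-9 relative). Both counts are rounded half-up;
since the continuous difference is integral, neutrality survives rounding
and is asserted. c₀ = 0 degenerates to pure neutralization. The water
volume is the periodic box volume (rhombic dodecahedron d³/√2 by default,
1 nm buffer) minus the protein volume, which is the sum of bundled mean
per-residue volumes in the spirit of Laguerre-tessellation averages; the
table documents its provenance and covers all bundled residue codes.

## Workflow artifact generation

All generators are pure text producers: identical inputs give
byte-identical output, and nothing is executed. Every default lives in the
single `DEFAULTS` table: the two-stage λ schedule (electrostatics first,
then vdW/bonded; λ = 0.00, 0.05, 0.10, 0.20, …, 0.90, 0.95, 1.00 — 13
values per stage with the fully-coupled boundary state shared, hence
13 + 12 = 25 one-ns legs), the minimization restraint ladder
1000/500/200/100/10/5/1 kJ mol⁻¹ nm⁻², 500 ps NVT at 300 K, a 20 ns
unrestrained NPT default (a long 500 ns NPT + 100 ns production preset is
kept alongside as `case_study_*`), docking exhaustiveness 64 with the
(19, 27, 16) Å two-ligand box floor, and the torsion-fit restraints above.
QM decks annotate the r²SCAN-D3(BJ)/def2-TZVP geometry/Hessian setup with
a 120-shell, order-41 angular grid, and the HF/6-31G* ESP setup with
capping-group charge constraints; the scan deck freezes φ, ψ and the
scanned dihedral.

## Analysis

* **Close contacts**: a residue qualifies when any of its atoms comes
  within 0.35 nm of any atom of the site residue in at least 70 % of the
  supplied frames; residues i±1 of the same chain are excluded (peptide
  bonds). The persistence denominator is all supplied frames —
  equilibration trimming is the caller's concern.
* **RMSF**: each frame is rigid-body fitted to the mean structure (single
  pass), then per-atom √⟨|x−⟨x⟩|²⟩ is taken. Removing the 6 rigid-body
  degrees of freedom biases isotropic-jitter RMSF down by roughly
  √(1 − 6/3N); the jitter oracle therefore uses a ≥ 10-residue chain where
  the bias is ~2 %.
* **BAR**: work is handled in kT (the Bennett equation is unit-free
  there; converters to kJ mol⁻¹ are provided). The self-consistency
  equation is solved by bracketed root finding to 1e-10; the uncertainty
  is the standard all-sample Fermi-overlap variance minus the sampling
  term. An overlap warning fires when the variance estimate diverges or
  exceeds (10 kT)². The Crooks-consistent Gaussian fixture
  (W_F ~ N(ΔG+σ²/2, σ²), W_B ~ N(−ΔG+σ²/2, σ²)) makes ΔG the exact
  asymptotic answer, giving a closed-form oracle; in the σ → 0 limit BAR
  agrees with exponential averaging (tested numerically).
* **Leg chaining** sums per-leg ΔG values, validates the count against a
  schedule and reports per-stage subtotals.

## Synthetic data and what passing tests show

The fixtures emulate the *mathematical* structure of QM/MD outputs — a
Hessian that is exactly the Gauss-Newton form of a diagonal harmonic force
field at equilibrium, an ESP that is exactly Coulombic, work samples that
satisfy the Crooks relation exactly, jitter with no correlations. Passing
tests therefore demonstrate that each estimator is a correct inverse of
its generative model at the stated tolerance; they do not demonstrate
accuracy on real electronic-structure data (anharmonicity, ESP fit
ambiguity, correlated dynamics), nor that generated engine inputs run on
any particular engine version. Problem sizes in the test suite and the
acceptance script (tri- to deca-peptides, 2000-frame trajectories, 1e5
work samples, 400-point ESP grids) were chosen so the full suite completes
in well under a minute while keeping Monte-Carlo error far below each
tolerance.

## Known limitations

Heavy atoms only (no protonation states); no rotamer libraries or
hydrogen-bond-aware scoring in the clash scan; no ring-closure or
chirality repair after editing; glutathionyl/cystine conformers get only
the generic chi scan; force-field parameters for CGL and IYY are not
derived (their templates exist for structure building only);
Lennard-Jones parameters are inherited from the base force field, never
derived; binary trajectory formats are not read — trajectories enter as
in-memory arrays or multi-model text.
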