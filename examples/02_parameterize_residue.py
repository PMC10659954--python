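"""Derive force-field parameters for a modified residue from synthetic data.

Shows each derivation route on inputs with known ground truth: a Seminario
bond constant from an analytic Hessian, RESP charges from an exact Coulomb
potential, and a torsion series refitted from its own energy profile; then
prints lines from the bundled S-nitrosocysteine set and its emitted
topology files.
"""

import numpy as np

from ptmforge.ff import (bundled_snc_parameters, fit_torsion_series, resp_fit,
                         seminario_bond, write_parameter_files)
from ptmforge.fixtures import (make_harmonic_hessian, make_point_charge_esp,
                               make_torsion_profile)

# Seminario: the interatomic Hessian block of a harmonic bond returns kb
h = make_harmonic_hessian(["C", "S"], [[0, 0, 0], [1.803, 0, 0]],
                          bonds=[(0, 1, 129555.1)])
term = seminario_bond(h, 0, 1)
print(f"Seminario bond: kb = {term.kb:.1f} kJ/mol/nm^2 at req = {term.req:.4f} nm"
      " (input constants recovered)")

# RESP: point charges are recovered from their own electrostatic potential
esp = make_point_charge_esp([0.3, -0.3], [[0, 0, 0], [2.0, 0, 0]], 400, seed=1)
charges = resp_fit([esp], restraint=0.0, formal_charge=0.0)
print(f"RESP charges: {charges['X1']:+.4f} / {charges['X2']:+.4f} e "
      "(generating values +0.3 / -0.3)")

# torsion series: refit the bundled C-S-N-O potential from its curve
snc = bundled_snc_parameters()
csno = snc.torsion("CB", "SG", "ND", "OE")
profile = make_torsion_profile(csno, np.arange(-180.0, 180.0, 10.0))
refit, rms = fit_torsion_series([profile], multiplicities=(1, 2, 3, 4))
print(f"torsion refit RMS residual: {rms:.2e} kJ/mol; "
      f"2-fold barrier {dict((t.n, t.k_phi) for t in refit.terms)[2]:.4f} kJ/mol")

files = write_parameter_files(snc)
print("\nemitted bonded parameters:")
print(files["ffbonded.itp"])
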