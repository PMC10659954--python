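"""Build a peptide, S-nitrosylate its cysteine, and write the result.

The modify step keeps every existing heavy atom, grows the S-nitroso
moiety (N and O on the sulfur) by internal-coordinate construction, and
renames the residue to SNC.
"""

from ptmforge import modify, write_pdb
from ptmforge.fixtures import make_toy_protein
from ptmforge.geometry import measure_internal

protein = make_toy_protein(3, ["GLY", "CYS", "GLY"])
modified = modify(protein, "A:CYS2", "nitrosylation")

res = modified.chain("A").residues[1]
print(f"residue 2 is now {res.name} with atoms {res.atom_names}")

ic = measure_internal(res.atom("CB").position, res.atom("SG").position,
                      res.atom("ND").position, res.atom("OE").position)
print(f"N-O bond {ic.r:.3f} A, S-N-O angle {ic.theta:.1f} deg "
      f"(the equilibrium geometry of the bundled parameter set)")

print(write_pdb(modified))
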