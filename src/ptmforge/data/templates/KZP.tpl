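# ptmforge residue template, schema v1 (SYNTHETIC)
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# Synthetic product template: no Chemical Component Dictionary code is in
# common use for this species, so the parent residue geometry is extended
# with an idealized phosphate group.
residue KZP
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4694  .       .
atom C    C  .    N    CA   1.5066  109.47  .
atom O    O  N    CA   C    1.2079  120.03  -20.01  
atom CB   C  C    N    CA   1.5300  109.45  -119.97 
atom CG   C  N    CA   CB   1.5307  109.42  -65.02  
atom CD   C  CA   CB   CG   1.5308  109.44  180.00  
atom CE   C  CB   CG   CD   1.5291  109.46  180.00  
atom NZ   N  CG   CD   CE   1.4694  109.50  -179.95 
atom P    P  CD   CE   NZ   1.6900  118.00  180.00
atom O1P  O  CE   NZ   P    1.4900  112.00  60.00
atom O2P  O  CE   NZ   P    1.4900  112.00  -60.00
atom O3P  O  CE   NZ   P    1.4900  112.00  180.00
chi1 N CA CB CG
chi2 CA CB CG CD
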