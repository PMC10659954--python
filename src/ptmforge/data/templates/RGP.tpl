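# ptmforge residue template, schema v1 (SYNTHETIC)
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# Synthetic product template: no Chemical Component Dictionary code is in
# common use for this species, so the parent residue geometry is extended
# with an idealized phosphate group.
residue RGP
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4618  .       .
atom C    C  .    N    CA   1.5181  108.14  .
atom O    O  N    CA   C    1.2241  125.48  -3.93   
atom CB   C  C    N    CA   1.5363  111.55  -123.56 
atom CG   C  N    CA   CB   1.5371  114.54  63.80   
atom CD   C  CA   CB   CG   1.5273  112.42  177.63  
atom NE   N  CB   CG   CD   1.4435  111.02  60.18   
atom CZ   C  CG   CD   NE   1.4058  123.00  179.98  
atom NH1  N  CD   NE   CZ   1.3905  121.00  179.99  
atom NH2  N  CD   NE   CZ   1.3912  119.81  -0.01   
atom P    P  NE   CZ   NH1  1.6900  118.00  180.00
atom O1P  O  CZ   NH1  P    1.4900  112.00  60.00
atom O2P  O  CZ   NH1  P    1.4900  112.00  -60.00
atom O3P  O  CZ   NH1  P    1.4900  112.00  180.00
chi1 N CA CB CG
chi2 CA CB CG CD
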