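# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue GLU
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4685  .       .
atom C    C  .    N    CA   1.5078  109.47  .
atom O    O  N    CA   C    1.2083  119.98  -19.98  
atom CB   C  C    N    CA   1.5302  109.48  -119.96 
atom CG   C  N    CA   CB   1.5306  109.40  -65.01  
atom CD   C  CA   CB   CG   1.5076  109.43  -180.00 
atom OE1  O  CB   CG   CD   1.2084  120.00  -0.03   
atom OE2  O  CB   CG   CD   1.3425  120.00  -179.97 
chi1 N CA CB CG
chi2 CA CB CG CD
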