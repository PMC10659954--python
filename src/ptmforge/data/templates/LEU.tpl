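# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue LEU
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4691  .       .
atom C    C  .    N    CA   1.5061  109.44  .
atom O    O  N    CA   C    1.2077  120.09  -29.98  
atom CB   C  C    N    CA   1.5286  109.42  -119.97 
atom CG   C  N    CA   CB   1.5303  109.49  -60.07  
atom CD1  C  CA   CB   CG   1.5300  109.50  179.99  
atom CD2  C  CA   CB   CG   1.5285  109.50  -59.92  
chi1 N CA CB CG
chi2 CA CB CG CD1
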