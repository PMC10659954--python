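# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue ILE
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4688  .       .
atom C    C  .    N    CA   1.5061  109.48  .
atom O    O  N    CA   C    1.2075  120.00  -30.06  
atom CB   C  C    N    CA   1.5288  109.43  -120.07 
atom CG1  C  N    CA   CB   1.5294  109.55  -59.99  
atom CG2  C  N    CA   CB   1.5303  109.46  -179.97 
atom CD1  C  CA   CB   CG1  1.5288  109.55  -180.00 
chi1 N CA CB CG1
chi2 CA CB CG1 CD1
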