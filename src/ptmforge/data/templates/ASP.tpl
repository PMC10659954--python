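# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue ASP
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4687  .       .
atom C    C  .    N    CA   1.5069  109.48  .
atom O    O  N    CA   C    1.2091  119.98  -20.02  
atom CB   C  C    N    CA   1.5301  109.48  -120.01 
atom CG   C  N    CA   CB   1.5075  109.46  -64.99  
atom OD1  O  CA   CB   CG   1.2080  119.96  -0.06   
atom OD2  O  CA   CB   CG   1.3415  120.00  -180.00 
chi1 N CA CB CG
chi2 CA CB CG OD1
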