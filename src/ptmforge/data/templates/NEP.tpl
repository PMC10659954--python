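# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue NEP
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4683  .       .
atom C    C  .    N    CA   1.5066  109.51  .
atom O    O  N    CA   C    1.2083  119.95  -30.01  
atom CB   C  C    N    CA   1.5292  109.50  -120.09 
atom CG   C  N    CA   CB   1.5070  109.47  -59.95  
atom ND1  N  CA   CB   CG   1.3408  126.01  -60.40  
atom CD2  C  CA   CB   CG   1.3457  125.96  119.99  
atom CE1  C  CB   CG   ND1  1.3032  109.28  179.92  
atom NE2  N  CB   CG   CD2  1.3689  106.82  179.95  
atom P    P  CG   CD2  NE2  1.6397  126.46  -179.98 
atom O1P  O  CD2  NE2  P    1.6083  109.54  179.97  
atom O2P  O  CD2  NE2  P    1.6101  109.44  -59.99  
atom O3P  O  CD2  NE2  P    1.4805  109.45  59.95   
chi1 N CA CB CG
chi2 CA CB CG ND1
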