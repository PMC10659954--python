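# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue 2MR
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4685  .       .
atom C    C  .    N    CA   1.5067  109.47  .
atom O    O  N    CA   C    1.2069  120.04  -29.99  
atom CB   C  C    N    CA   1.5294  109.44  -120.03 
atom CG   C  N    CA   CB   1.5298  109.52  -59.96  
atom CD   C  CA   CB   CG   1.5284  109.50  -179.96 
atom NE   N  CB   CG   CD   1.4649  109.52  -180.00 
atom CZ   C  CG   CD   NE   1.3751  120.04  -175.05 
atom NH1  N  CD   NE   CZ   1.3027  120.02  174.79  
atom CQ1  C  NE   CZ   NH1  1.4656  119.97  5.23    
atom NH2  N  CD   NE   CZ   1.3743  120.00  -5.16   
atom CQ2  C  NE   CZ   NH2  1.4646  120.01  -180.00 
chi1 N CA CB CG
chi2 CA CB CG CD
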