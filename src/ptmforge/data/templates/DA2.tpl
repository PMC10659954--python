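# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue DA2
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4696  .       .
atom C    C  .    N    CA   1.5076  109.42  .
atom O    O  N    CA   C    1.2081  120.03  -19.98  
atom CB   C  C    N    CA   1.5289  109.49  -119.98 
atom CG   C  N    CA   CB   1.5307  109.47  -65.05  
atom CD   C  CA   CB   CG   1.5297  109.50  -180.00 
atom NE   N  CB   CG   CD   1.4644  109.47  -180.00 
atom CZ   C  CG   CD   NE   1.3758  119.99  -179.99 
atom NH2  N  CD   NE   CZ   1.3033  120.00  0.00    
atom NH1  N  CD   NE   CZ   1.3745  119.98  -180.00 
atom C1   C  NE   CZ   NH1  1.4647  119.99  179.98  
atom C2   C  NE   CZ   NH1  1.4653  120.00  0.04    
chi1 N CA CB CG
chi2 CA CB CG CD
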