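# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue M3L
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4689  .       .
atom C    C  .    N    CA   1.5075  109.47  .
atom O    O  N    CA   C    1.2078  119.97  -20.06  
atom CB   C  C    N    CA   1.5298  109.48  -120.02 
atom CG   C  N    CA   CB   1.5306  109.46  -65.01  
atom CD   C  CA   CB   CG   1.5298  109.46  180.00  
atom CE   C  CB   CG   CD   1.5301  109.48  -179.97 
atom NZ   N  CG   CD   CE   1.4685  109.46  -179.97 
atom CM1  C  CD   CE   NZ   1.4691  109.50  60.02   
atom CM2  C  CD   CE   NZ   1.4689  109.47  -60.04  
atom CM3  C  CD   CE   NZ   1.4697  109.44  179.99  
chi1 N CA CB CG
chi2 CA CB CG CD
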