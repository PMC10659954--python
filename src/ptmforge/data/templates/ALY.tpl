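# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue ALY
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4684  .       .
atom C    C  .    N    CA   1.5071  109.45  .
atom O    O  N    CA   C    1.2079  120.01  -29.97  
atom CB   C  C    N    CA   1.5299  109.46  -120.03 
atom CG   C  N    CA   CB   1.5289  109.56  -59.97  
atom CD   C  CA   CB   CG   1.5281  109.53  -179.97 
atom CE   C  CB   CG   CD   1.5294  109.50  -179.98 
atom NZ   N  CG   CD   CE   1.4649  109.55  179.98  
atom CH   C  CD   CE   NZ   1.3474  120.04  179.95  
atom CH3  C  CE   NZ   CH   1.5072  119.95  179.98  
atom OH   O  CE   NZ   CH   1.2113  120.01  0.04    
chi1 N CA CB CG
chi2 CA CB CG CD
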