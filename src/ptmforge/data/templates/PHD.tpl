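# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue PHD
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4691  .       .
atom C    C  .    N    CA   1.5060  109.46  .
atom O    O  N    CA   C    1.2085  120.01  -30.15  
atom CB   C  C    N    CA   1.5285  109.45  -120.16 
atom CG   C  N    CA   CB   1.5057  109.55  -59.94  
atom OD1  O  CA   CB   CG   1.3424  120.06  179.99  
atom OD2  O  CA   CB   CG   1.2071  120.02  -0.05   
atom P    P  CB   CG   OD1  1.6094  120.05  179.95  
atom OP1  O  CG   OD1  P    1.4795  109.45  60.05   
atom OP2  O  CG   OD1  P    1.6102  109.48  179.99  
atom OP3  O  CG   OD1  P    1.6085  109.51  -59.97  
chi1 N CA CB CG
chi2 CA CB CG OD1
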