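# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue PTR
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4681  .       .
atom C    C  .    N    CA   1.5075  109.47  .
atom O    O  N    CA   C    1.2067  120.00  -30.07  
atom CB   C  C    N    CA   1.5290  109.48  -120.05 
atom CG   C  N    CA   CB   1.5069  109.47  -59.98  
atom CD1  C  CA   CB   CG   1.3820  119.94  90.03   
atom CD2  C  CA   CB   CG   1.3822  119.93  -90.35  
atom CE1  C  CB   CG   CD1  1.3808  120.05  179.94  
atom CE2  C  CB   CG   CD2  1.3813  120.05  179.71  
atom CZ   C  CG   CD1  CE1  1.3869  119.94  0.04    
atom OH   O  CD1  CE1  CZ   1.3588  120.05  179.95  
atom P    P  CE1  CZ   OH   1.6092  106.84  89.93   
atom O1P  O  CZ   OH   P    1.4807  109.39  60.02   
atom O2P  O  CZ   OH   P    1.6097  109.54  179.95  
atom O3P  O  CZ   OH   P    1.6082  109.51  -59.92  
chi1 N CA CB CG
chi2 CA CB CG CD1
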