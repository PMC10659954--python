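# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue TRP
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4688  .       .
atom C    C  .    N    CA   1.5074  109.43  .
atom O    O  N    CA   C    1.2079  120.00  -30.00  
atom CB   C  C    N    CA   1.5286  109.52  -120.03 
atom CG   C  N    CA   CB   1.5067  109.44  -60.00  
atom CD1  C  CA   CB   CG   1.3426  126.50  90.04   
atom CD2  C  CA   CB   CG   1.4639  126.51  -90.34  
atom NE1  N  CB   CG   CD1  1.3686  109.93  179.94  
atom CE2  C  CB   CG   CD2  1.4068  106.08  179.96  
atom CE3  C  CB   CG   CD2  1.3961  134.05  0.78    
atom CZ2  C  CG   CD2  CE2  1.3906  119.35  -179.83 
atom CZ3  C  CG   CD2  CE3  1.3659  119.80  179.64  
atom CH2  C  CD2  CE2  CZ2  1.3773  119.81  0.22    
chi1 N CA CB CG
chi2 CA CB CG CD1
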