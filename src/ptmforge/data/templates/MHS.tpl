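# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue MHS
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4695  .       .
atom C    C  .    N    CA   1.5071  109.40  .
atom O    O  N    CA   C    1.2069  120.05  -29.93  
atom CB   C  C    N    CA   1.5292  109.43  -119.95 
atom CG   C  N    CA   CB   1.5062  109.47  -60.09  
atom ND1  N  CA   CB   CG   1.3682  126.65  -90.47  
atom CD2  C  CA   CB   CG   1.3465  126.58  90.03   
atom CE1  C  CB   CG   ND1  1.3505  107.24  -179.99 
atom NE2  N  CB   CG   CD2  1.3403  108.05  179.97  
atom CM   C  CB   CG   ND1  1.4651  126.36  0.29    
chi1 N CA CB CG
chi2 CA CB CG ND1
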