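# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue HIS
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4411  .       .
atom C    C  .    N    CA   1.5218  111.15  .
atom O    O  N    CA   C    1.2269  122.98  -34.46  
atom CB   C  C    N    CA   1.5337  111.13  -122.78 
atom CG   C  N    CA   CB   1.5100  112.98  -158.20 
atom ND1  N  CA   CB   CG   1.3513  120.33  -90.01  
atom CD2  C  CA   CB   CG   1.3376  129.93  89.84   
atom CE1  C  CB   CG   ND1  1.3369  107.86  179.90  
atom NE2  N  CB   CG   CD2  1.3739  105.33  -179.86 
chi1 N CA CB CG
chi2 CA CB CG ND1
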