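# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue PHE
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4686  .       .
atom C    C  .    N    CA   1.5071  109.49  .
atom O    O  N    CA   C    1.2070  119.98  -30.06  
atom CB   C  C    N    CA   1.5289  109.47  -120.09 
atom CG   C  N    CA   CB   1.5052  109.52  -59.93  
atom CD1  C  CA   CB   CG   1.3817  120.06  89.97   
atom CD2  C  CA   CB   CG   1.3832  120.00  -90.27  
atom CE1  C  CB   CG   CD1  1.3820  120.03  179.99  
atom CE2  C  CB   CG   CD2  1.3819  119.98  179.84  
atom CZ   C  CG   CD1  CE1  1.3806  120.05  -0.05   
chi1 N CA CB CG
chi2 CA CB CG CD1
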