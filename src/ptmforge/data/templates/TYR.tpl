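# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue TYR
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4688  .       .
atom C    C  .    N    CA   1.5072  109.47  .
atom O    O  N    CA   C    1.2070  120.01  -29.98  
atom CB   C  C    N    CA   1.5287  109.47  -120.04 
atom CG   C  N    CA   CB   1.5062  109.50  -59.98  
atom CD1  C  CA   CB   CG   1.3823  119.95  90.03   
atom CD2  C  CA   CB   CG   1.3830  119.94  -90.28  
atom CE1  C  CB   CG   CD1  1.3810  120.07  -179.98 
atom CE2  C  CB   CG   CD2  1.3809  120.02  179.77  
atom CZ   C  CG   CD1  CE1  1.3867  119.98  -0.10   
atom OH   O  CD1  CE1  CZ   1.3582  120.13  -179.97 
chi1 N CA CB CG
chi2 CA CB CG CD1
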