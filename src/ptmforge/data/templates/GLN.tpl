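# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue GLN
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4688  .       .
atom C    C  .    N    CA   1.5063  109.45  .
atom O    O  N    CA   C    1.2072  120.03  -30.01  
atom CB   C  C    N    CA   1.5288  109.46  -120.07 
atom CG   C  N    CA   CB   1.5284  109.53  -59.92  
atom CD   C  CA   CB   CG   1.5066  109.54  -179.99 
atom OE1  O  CB   CG   CD   1.2122  119.94  -0.05   
atom NE2  N  CB   CG   CD   1.3471  120.09  179.99  
chi1 N CA CB CG
chi2 CA CB CG CD
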