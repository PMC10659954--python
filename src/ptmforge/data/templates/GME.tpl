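# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue GME
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4697  .       .
atom C    C  .    N    CA   1.5068  109.45  .
atom O    O  N    CA   C    1.2088  120.04  -20.00  
atom CB   C  C    N    CA   1.5302  109.46  -119.98 
atom CG   C  N    CA   CB   1.5303  109.46  -65.03  
atom CD   C  CA   CB   CG   1.5065  109.45  -179.97 
atom OE1  O  CB   CG   CD   1.2079  120.04  0.04    
atom OE2  O  CB   CG   CD   1.3430  119.96  180.00  
atom CX   C  CG   CD   OE2  1.4520  116.95  179.99  
chi1 N CA CB CG
chi2 CA CB CG CD
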