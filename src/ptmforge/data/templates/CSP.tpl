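# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue CSP
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4691  .       .
atom C    C  .    N    CA   1.5059  109.49  .
atom O    O  N    CA   C    1.2090  119.98  -30.03  
atom CB   C  C    N    CA   1.5305  109.44  -120.03 
atom SG   S  N    CA   CB   1.8127  109.49  -60.03  
atom P    P  CA   CB   SG   2.1189  100.02  -179.96 
atom O1P  O  CB   SG   P    1.4801  109.51  59.97   
atom O2P  O  CB   SG   P    1.6090  109.56  -179.96 
atom O3P  O  CB   SG   P    1.6096  109.45  -59.97  
chi1 N CA CB SG
chi2 CA CB SG P
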