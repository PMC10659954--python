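# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue IYY
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4686  .       .
atom C    C  .    N    CA   1.5077  109.49  .
atom O    O  N    CA   C    1.2078  120.01  -19.94  
atom CB   C  C    N    CA   1.5295  109.50  -119.98 
atom SG   S  N    CA   CB   1.8132  109.48  -65.52  
atom S1   S  CA   CB   SG   2.0502  103.03  76.84   
atom C3   C  CB   SG   S1   1.8146  102.99  85.00   
atom C4   C  SG   S1   C3   1.5304  109.43  70.02   
atom C5   C  S1   C3   C4   1.5067  109.44  -180.00 
atom O2   O  C3   C4   C5   1.2079  120.02  100.07  
atom N1   N  S1   C3   C4   1.4680  109.49  -59.99  
atom O3   O  C3   C4   C5   1.3430  120.00  -80.00  
chi1 N CA CB SG
chi2 CA CB SG S1
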