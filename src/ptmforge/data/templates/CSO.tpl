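# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue CSO
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4682  .       .
atom C    C  .    N    CA   1.5069  109.51  .
atom O    O  N    CA   C    1.2086  119.96  -20.07  
atom CB   C  C    N    CA   1.5297  109.51  -120.07 
atom SG   S  N    CA   CB   1.8138  109.48  -59.95  
atom OD   O  CA   CB   SG   1.5218  103.02  74.95   
chi1 N CA CB SG
chi2 CA CB SG OD
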