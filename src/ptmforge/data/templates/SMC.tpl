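# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue SMC
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4691  .       .
atom C    C  .    N    CA   1.5059  109.48  .
atom O    O  N    CA   C    1.2075  120.04  -30.04  
atom CB   C  C    N    CA   1.5290  109.45  -120.06 
atom SG   S  N    CA   CB   1.8131  109.52  -59.95  
atom CS   C  CA   CB   SG   1.8134  100.05  179.99  
chi1 N CA CB SG
chi2 CA CB SG CS
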