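# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue XCN
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4685  .       .
atom C    C  .    N    CA   1.5071  109.47  .
atom O    O  N    CA   C    1.2084  119.97  -20.30  
atom CB   C  C    N    CA   1.5295  109.48  -120.04 
atom SG   S  N    CA   CB   1.8103  109.51  -59.97  
atom CS   C  CA   CB   SG   1.8097  100.00  179.99  
atom NC   N  CB   SG   CS   1.1356  179.50  129.21  
chi1 N CA CB SG
chi2 CA CB SG CS
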