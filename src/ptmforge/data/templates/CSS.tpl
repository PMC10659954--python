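# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue CSS
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4688  .       .
atom C    C  .    N    CA   1.5059  109.50  .
atom O    O  N    CA   C    1.2081  119.98  -29.98  
atom CB   C  C    N    CA   1.5295  109.44  -120.01 
atom SG   S  N    CA   CB   1.8131  109.49  178.89  
atom SD   S  CA   CB   SG   2.0495  100.04  75.00   
chi1 N CA CB SG
chi2 CA CB SG SD
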