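# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue CSD
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4685  .       .
atom C    C  .    N    CA   1.5071  109.48  .
atom O    O  N    CA   C    1.2085  119.98  -20.01  
atom CB   C  C    N    CA   1.5307  109.48  -119.99 
atom SG   S  N    CA   CB   1.8142  109.45  -60.02  
atom OD1  O  CA   CB   SG   1.4209  109.45  70.95   
atom OD2  O  CA   CB   SG   1.5221  102.97  180.00  
chi1 N CA CB SG
chi2 CA CB SG OD1
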