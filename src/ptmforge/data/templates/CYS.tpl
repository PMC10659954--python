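# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue CYS
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4688  .       .
atom C    C  .    N    CA   1.5064  109.39  .
atom O    O  N    CA   C    1.2068  120.06  -30.02  
atom CB   C  C    N    CA   1.5285  109.50  -120.01 
atom SG   S  N    CA   CB   1.8141  109.50  -60.00  
chi1 N CA CB SG
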