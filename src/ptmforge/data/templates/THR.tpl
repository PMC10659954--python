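# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue THR
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4694  .       .
atom C    C  .    N    CA   1.5061  109.41  .
atom O    O  N    CA   C    1.2071  120.09  -30.02  
atom CB   C  C    N    CA   1.5290  109.41  -120.00 
atom OG1  O  N    CA   CB   1.4280  109.51  60.02   
atom CG2  C  N    CA   CB   1.5301  109.53  -60.01  
chi1 N CA CB OG1
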