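# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue ALA
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4677  .       .
atom C    C  .    N    CA   1.5055  109.52  .
atom O    O  N    CA   C    1.2070  120.03  -29.90  
atom CB   C  C    N    CA   1.5294  109.46  -120.00 
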