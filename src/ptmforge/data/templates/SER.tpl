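# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue SER
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4690  .       .
atom C    C  .    N    CA   1.5067  109.44  .
atom O    O  N    CA   C    1.2069  120.05  -30.01  
atom CB   C  C    N    CA   1.5287  109.47  -120.02 
atom OG   O  N    CA   CB   1.4283  109.51  -59.97  
chi1 N CA CB OG
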