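# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue ACE
role CA CH3
role C C
role O O
atom CH3  C  .    .    .    .       .       .
atom C    C  .    .    CH3  1.5074  .       .
atom O    O  .    CH3  C    1.2072  119.98  .
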