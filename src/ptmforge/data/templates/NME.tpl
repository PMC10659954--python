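# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue NME
role N N
role CA C
atom N    N  .    .    .    .       .       .
atom C    C  .    .    N    1.4691  .       .
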