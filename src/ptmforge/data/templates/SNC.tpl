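# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates, S-nitroso moiety equilibria from the bundled SNC parameter set
residue SNC
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4690  .       .
atom C    C  .    N    CA   1.5061  109.43  .
atom O    O  N    CA   C    1.2071  120.05  -30.10  
atom CB   C  C    N    CA   1.5281  109.42  -120.06 
atom SG   S  N    CA   CB   1.8030  113.80  -60.00  
atom ND   N  CA   CB   SG   1.9180  99.50   -179.96 
atom OE   O  CB   SG   ND   1.1700  117.20  180.00  
chi1 N CA CB SG
chi2 CA CB SG ND
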