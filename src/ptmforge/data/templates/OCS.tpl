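# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue OCS
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4693  .       .
atom C    C  .    N    CA   1.5071  109.45  .
atom O    O  N    CA   C    1.2075  120.03  -19.95  
atom CB   C  C    N    CA   1.5297  109.45  -119.96 
atom SG   S  N    CA   CB   1.8143  109.47  -60.03  
atom OD1  O  CA   CB   SG   1.4206  110.55  68.40   
atom OD2  O  CA   CB   SG   1.5215  104.45  -179.97 
atom OD3  O  CA   CB   SG   1.4213  110.53  -68.35  
chi1 N CA CB SG
chi2 CA CB SG OD1
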