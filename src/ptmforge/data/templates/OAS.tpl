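# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue OAS
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4695  .       .
atom C    C  .    N    CA   1.5070  109.47  .
atom O    O  N    CA   C    1.2068  120.03  -30.08  
atom CB   C  C    N    CA   1.5283  109.46  -120.08 
atom OG   O  N    CA   CB   1.4505  109.56  -59.95  
atom C1A  C  CA   CB   OG   1.3416  120.10  -179.98 
atom OAC  O  CB   OG   C1A  1.2084  119.96  -0.06   
atom C2A  C  CB   OG   C1A  1.5067  120.11  -179.98 
chi1 N CA CB OG
chi2 CA CB OG C1A
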