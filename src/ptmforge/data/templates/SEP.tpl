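# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue SEP
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4689  .       .
atom C    C  .    N    CA   1.5059  109.42  .
atom O    O  N    CA   C    1.2085  120.02  -30.11  
atom CB   C  C    N    CA   1.5288  109.45  -120.08 
atom OG   O  N    CA   CB   1.4279  109.51  -60.08  
atom P    P  CA   CB   OG   1.6093  106.84  -179.98 
atom O1P  O  CB   OG   P    1.4796  109.46  60.02   
atom O2P  O  CB   OG   P    1.6099  109.53  -179.94 
atom O3P  O  CB   OG   P    1.6094  109.47  -59.91  
chi1 N CA CB OG
chi2 CA CB OG P
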