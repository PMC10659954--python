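# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue ASN
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4682  .       .
atom C    C  .    N    CA   1.5072  109.51  .
atom O    O  N    CA   C    1.2079  119.97  -19.97  
atom CB   C  C    N    CA   1.5309  109.45  -120.00 
atom CG   C  N    CA   CB   1.5066  109.48  -64.95  
atom OD1  O  CA   CB   CG   1.2133  119.97  -0.06   
atom ND2  N  CA   CB   CG   1.3476  120.01  -179.98 
chi1 N CA CB CG
chi2 CA CB CG OD1
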