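# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue VAL
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4688  .       .
atom C    C  .    N    CA   1.5059  109.46  .
atom O    O  N    CA   C    1.2075  120.02  -30.00  
atom CB   C  C    N    CA   1.5287  109.45  -120.00 
atom CG1  C  N    CA   CB   1.5299  109.51  -59.99  
atom CG2  C  N    CA   CB   1.5292  109.49  60.03   
chi1 N CA CB CG1
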