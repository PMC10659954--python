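# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue QCS
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4689  .       .
atom C    C  .    N    CA   1.5068  109.45  .
atom O    O  N    CA   C    1.2082  120.01  -20.01  
atom CB   C  C    N    CA   1.5296  109.46  -120.02 
atom SG   S  N    CA   CB   1.8098  109.49  -59.98  
atom CD   C  CA   CB   SG   1.7626  100.00  -179.98 
atom NE2  N  CB   SG   CD   1.3474  119.97  -179.98 
atom OE1  O  CB   SG   CD   1.2160  120.00  -0.05   
chi1 N CA CB SG
chi2 CA CB SG CD
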