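# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue NMM
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4692  .       .
atom C    C  .    N    CA   1.5066  109.50  .
atom O    O  N    CA   C    1.2077  120.03  -20.02  
atom CB   C  C    N    CA   1.5300  109.44  -120.03 
atom CG   C  N    CA   CB   1.5298  109.48  -64.93  
atom CD   C  CA   CB   CG   1.5305  109.46  -179.98 
atom NE   N  CB   CG   CD   1.4655  109.47  179.99  
atom CZ   C  CG   CD   NE   1.3747  120.00  -179.97 
atom NH1  N  CD   NE   CZ   1.3033  120.00  -0.07   
atom NH2  N  CD   NE   CZ   1.3750  120.00  -179.99 
atom CAA  C  NE   CZ   NH2  1.4645  120.02  179.96  
chi1 N CA CB CG
chi2 CA CB CG CD
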