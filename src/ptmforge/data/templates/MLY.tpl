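# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue MLY
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4694  .       .
atom C    C  .    N    CA   1.5057  109.48  .
atom O    O  N    CA   C    1.2079  120.02  -30.07  
atom CB   C  C    N    CA   1.5299  109.43  -120.10 
atom CG   C  N    CA   CB   1.5282  109.52  -59.94  
atom CD   C  CA   CB   CG   1.5295  109.54  -179.97 
atom CE   C  CB   CG   CD   1.5286  109.58  179.98  
atom NZ   N  CG   CD   CE   1.4681  109.54  179.92  
atom CH1  C  CD   CE   NZ   1.4687  106.76  179.96  
atom CH2  C  CD   CE   NZ   1.4680  106.76  -66.18  
chi1 N CA CB CG
chi2 CA CB CG CD
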