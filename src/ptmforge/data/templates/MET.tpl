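# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue MET
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4689  .       .
atom C    C  .    N    CA   1.5062  109.43  .
atom O    O  N    CA   C    1.2072  120.05  -30.02  
atom CB   C  C    N    CA   1.5294  109.43  -120.04 
atom CG   C  N    CA   CB   1.5284  109.54  -60.02  
atom SD   S  CA   CB   CG   1.8137  109.51  -179.98 
atom CE   C  CB   CG   SD   1.8135  100.03  -180.00 
chi1 N CA CB CG
chi2 CA CB CG SD
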