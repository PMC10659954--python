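# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue MLZ
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4401  .       .
atom C    C  .    N    CA   1.5158  106.48  .
atom O    O  N    CA   C    1.2240  125.28  -35.74  
atom CB   C  C    N    CA   1.5297  112.45  -120.75 
atom CG   C  N    CA   CB   1.5340  114.69  -62.89  
atom CD   C  CA   CB   CG   1.5325  113.26  -177.74 
atom CE   C  CB   CG   CD   1.5305  112.94  -177.57 
atom NZ   N  CG   CD   CE   1.4578  111.92  178.33  
atom CM   C  CD   CE   NZ   1.4556  110.93  -177.93 
chi1 N CA CB CG
chi2 CA CB CG CD
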