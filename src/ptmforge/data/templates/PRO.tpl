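# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue PRO
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4862  .       .
atom C    C  .    N    CA   1.5076  110.38  .
atom O    O  N    CA   C    1.2085  119.99  -16.99  
atom CB   C  C    N    CA   1.5434  104.72  -118.84 
atom CG   C  N    CA   CB   1.5426  105.06  -23.80  
atom CD   C  C    CA   N    1.4866  104.14  158.14  
chi1 N CA CB CG
chi2 CA CB CG CD
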