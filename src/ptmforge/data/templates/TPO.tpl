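# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue TPO
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4686  .       .
atom C    C  .    N    CA   1.5054  109.49  .
atom O    O  N    CA   C    1.2071  120.03  -30.07  
atom CB   C  C    N    CA   1.5301  109.45  -120.06 
atom CG2  C  N    CA   CB   1.5295  109.51  -59.95  
atom OG1  O  N    CA   CB   1.4280  109.45  60.08   
atom P    P  CA   CB   OG1  1.6094  106.79  119.97  
atom O1P  O  CB   OG1  P    1.4798  109.50  60.01   
atom O2P  O  CB   OG1  P    1.6100  109.46  179.96  
atom O3P  O  CB   OG1  P    1.6098  109.47  -60.02  
chi1 N CA CB CG2
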