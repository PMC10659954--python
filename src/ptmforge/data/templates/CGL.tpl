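# ptmforge residue template, schema v1
# columns: atom <name> <element> <ref_a> <ref_b> <ref_c> <r_A> <theta_deg> <phi_deg>
# heavy atoms only; geometry from Chemical Component Dictionary ideal
# coordinates
residue CGL
role N N
role CA CA
role C C
role O O
atom N    N  .    .    .    .       .       .
atom CA   C  .    .    N    1.4693  .       .
atom C    C  .    N    CA   1.5065  109.46  .
atom O    O  N    CA   C    1.2080  120.02  -19.98  
atom CB   C  C    N    CA   1.5303  109.45  -119.98 
atom SG   S  N    CA   CB   1.8142  109.46  -65.25  
atom SG2  S  CA   CB   SG   2.0508  102.99  77.20   
atom CB2  C  CB   SG   SG2  1.8143  103.00  84.99   
atom CA2  C  SG   SG2  CB2  1.5297  109.46  70.00   
atom C2   C  SG2  CB2  CA2  1.5069  109.45  179.99  
atom O2   O  CB2  CA2  C2   1.2137  120.00  120.03  
atom N3   N  CB2  CA2  C2   1.3476  120.03  -60.00  
atom CA3  C  CA2  C2   N3   1.4644  120.03  179.99  
atom C3   C  C2   N3   CA3  1.5072  109.48  -179.99 
atom O31  O  N3   CA3  C3   1.2077  119.99  0.04    
atom O32  O  N3   CA3  C3   1.3425  119.99  -179.98 
atom N2   N  SG2  CB2  CA2  1.4652  109.50  -60.02  
atom CD1  C  CB2  CA2  N2   1.3477  119.99  154.99  
atom OE1  O  CA2  N2   CD1  1.2128  120.04  0.01    
atom CG1  C  CA2  N2   CD1  1.5072  119.98  -179.98 
atom CB1  C  N2   CD1  CG1  1.5298  109.47  180.00  
atom CA1  C  CD1  CG1  CB1  1.5303  109.47  179.99  
atom C1   C  CG1  CB1  CA1  1.5072  109.44  175.01  
atom O11  O  CB1  CA1  C1   1.2088  119.99  100.03  
atom O12  O  CB1  CA1  C1   1.3427  120.02  -80.02  
atom N1   N  CG1  CB1  CA1  1.4692  109.47  -64.99  
chi1 N CA CB SG
chi2 CA CB SG SG2
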