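# Bundled force-field parameter set for S-nitroso-L-cysteine (SNC),
# FF99SB-compatible. Units: charges e; bond req nm, kb kJ mol^-1 nm^-2;
# angle theta_eq deg, k_theta kJ mol^-1 rad^-2; torsion k_phi kJ mol^-1,
# phase deg, n multiplicity. One row per tabulated term; HB1 stands for
# either beta hydrogen.
# record types: charge,<atom>,<q> | bond,<a>,<b>,<req>,<kb> |
# angle,<a>,<b>,<c>,<theta_eq>,<k_theta>,<corrected|uncorrected> |
# torsion,<a>,<b>,<c>,<d>,<phase_deg>,<k_phi>,<n> | atomtype,<atom>,<type>
charge,CA,-0.0218
charge,HA,0.0758
charge,CB,0.4533
charge,HB1,-0.0674
charge,HB2,-0.0674
charge,SG,-0.1959
charge,ND,0.0855
charge,OE,-0.1468
bond,CB,SG,0.1803,129555.1
bond,SG,ND,0.1918,79743.2
bond,ND,OE,0.1170,695768.8
angle,HB1,CB,SG,107.5,293.0,corrected
angle,CA,CB,SG,113.8,487.5,corrected
angle,CB,SG,ND,99.5,1137.0,uncorrected
angle,SG,ND,OE,117.2,1283.1,uncorrected
torsion,CA,CB,SG,ND,180,0.2399,1
torsion,CA,CB,SG,ND,0,1.4742,2
torsion,HB1,CB,SG,ND,180,1.4613,3
torsion,CB,SG,ND,OE,0,1.0769,1
torsion,CB,SG,ND,OE,180,27.2930,2
torsion,CB,SG,ND,OE,180,2.7214,3
torsion,CB,SG,ND,OE,180,0.5033,4
atomtype,CA,CT
atomtype,HA,H1
atomtype,CB,CT
atomtype,HB1,H1
atomtype,HB2,H1
atomtype,SG,S
atomtype,ND,NO
atomtype,OE,ON
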