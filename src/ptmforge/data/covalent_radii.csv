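# Single-bond covalent radii in Angstrom (Cordero et al., Dalton Trans. 2008).
# For carbon the sp3 value is used.
element,radius
H,0.31
B,0.84
C,0.76
N,0.71
O,0.66
F,0.57
Na,1.66
Mg,1.41
Si,1.11
P,1.07
S,1.05
Cl,1.02
K,2.03
Ca,1.76
Mn,1.39
Fe,1.32
Co,1.26
Ni,1.24
Cu,1.32
Zn,1.22
Se,1.20
Br,1.20
I,1.39
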