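# Mean per-residue volumes in Angstrom^3 for protein-volume estimation,
# in the spirit of Laguerre-tessellation averages over folded proteins
# (standard-residue values from the Voronoi/Laguerre literature; modified
# residues are standard-residue values incremented by group volumes).
residue,volume_A3
2MR,256.0
ACE,72.0
ALA,91.5
ALY,231.0
ARG,196.1
ASN,126.5
ASP,120.1
CGL,400.0
CSD,136.0
CSO,121.0
CSP,191.0
CSS,138.0
CYS,105.6
DA2,256.0
GLN,151.0
GLU,148.8
GLY,66.5
GME,179.0
HIS,167.0
ILE,162.6
IYY,220.0
KZP,258.0
LEU,163.4
LYS,172.7
M3L,263.0
MET,165.9
MHS,197.0
MLY,233.0
MLZ,203.0
NEP,252.0
NME,62.0
NMM,226.0
OAS,164.0
OCS,151.0
PHD,205.0
PHE,198.8
PRO,123.4
PTR,295.0
QCS,160.0
RGP,281.0
SEP,184.0
SER,99.1
SMC,136.0
SNC,133.0
THR,122.1
TPO,207.0
TRP,237.2
TYR,209.8
VAL,138.4
XCN,140.0
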