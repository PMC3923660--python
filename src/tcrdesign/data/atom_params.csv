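atom_type,charge,lj_radius,lj_well_depth,dg_free,lambda,volume
ALA:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
ALA:H,0.25,0.8,0.0498,0.0,3.5,0.0
ALA:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
ALA:C,0.55,2.1,0.12,0.0,3.5,14.7
ALA:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
ALA:CB,0.0,2.165,0.1811,1.089,3.5,30.0
ARG:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
ARG:H,0.25,0.8,0.0498,0.0,3.5,0.0
ARG:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
ARG:C,0.55,2.1,0.12,0.0,3.5,14.7
ARG:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
ARG:CB,0.0,2.235,0.1142,0.372,3.5,22.4
ARG:CG,0.0,2.235,0.1142,0.372,3.5,22.4
ARG:CD,0.1,2.235,0.1142,0.372,3.5,22.4
ARG:NE,-0.4,1.6,0.2384,-5.95,3.5,4.4
ARG:HE,0.3,0.8,0.0498,0.0,3.5,0.0
ARG:CZ,0.5,2.1,0.12,0.0,3.5,14.7
ARG:NH1,-0.45,1.6,0.2384,-10.0,6.0,11.2
ARG:HH11,0.35,0.8,0.0498,0.0,3.5,0.0
ARG:HH12,0.35,0.8,0.0498,0.0,3.5,0.0
ARG:NH2,-0.45,1.6,0.2384,-10.0,6.0,11.2
ARG:HH21,0.35,0.8,0.0498,0.0,3.5,0.0
ARG:HH22,0.35,0.8,0.0498,0.0,3.5,0.0
ASN:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
ASN:H,0.25,0.8,0.0498,0.0,3.5,0.0
ASN:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
ASN:C,0.55,2.1,0.12,0.0,3.5,14.7
ASN:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
ASN:CB,0.0,2.235,0.1142,0.372,3.5,22.4
ASN:CG,0.55,2.1,0.12,0.0,3.5,14.7
ASN:OD1,-0.55,1.6,0.1591,-5.33,3.5,10.8
ASN:ND2,-0.6,1.6,0.2384,-5.45,3.5,11.2
ASN:HD21,0.3,0.8,0.0498,0.0,3.5,0.0
ASN:HD22,0.3,0.8,0.0498,0.0,3.5,0.0
ASP:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
ASP:H,0.25,0.8,0.0498,0.0,3.5,0.0
ASP:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
ASP:C,0.55,2.1,0.12,0.0,3.5,14.7
ASP:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
ASP:CB,-0.16,2.235,0.1142,0.372,3.5,22.4
ASP:CG,0.36,2.1,0.12,0.0,3.5,14.7
ASP:OD1,-0.6,1.6,0.6469,-10.0,6.0,10.8
ASP:OD2,-0.6,1.6,0.6469,-10.0,6.0,10.8
CYS:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
CYS:H,0.25,0.8,0.0498,0.0,3.5,0.0
CYS:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
CYS:C,0.55,2.1,0.12,0.0,3.5,14.7
CYS:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
CYS:CB,0.19,2.235,0.1142,0.372,3.5,22.4
CYS:SG,-0.19,1.89,0.043,-2.05,3.5,21.4
GLN:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
GLN:H,0.25,0.8,0.0498,0.0,3.5,0.0
GLN:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
GLN:C,0.55,2.1,0.12,0.0,3.5,14.7
GLN:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
GLN:CB,0.0,2.235,0.1142,0.372,3.5,22.4
GLN:CG,0.0,2.235,0.1142,0.372,3.5,22.4
GLN:CD,0.55,2.1,0.12,0.0,3.5,14.7
GLN:OE1,-0.55,1.6,0.1591,-5.33,3.5,10.8
GLN:NE2,-0.6,1.6,0.2384,-5.45,3.5,11.2
GLN:HE21,0.3,0.8,0.0498,0.0,3.5,0.0
GLN:HE22,0.3,0.8,0.0498,0.0,3.5,0.0
GLU:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
GLU:H,0.25,0.8,0.0498,0.0,3.5,0.0
GLU:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
GLU:C,0.55,2.1,0.12,0.0,3.5,14.7
GLU:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
GLU:CB,0.0,2.235,0.1142,0.372,3.5,22.4
GLU:CG,-0.16,2.235,0.1142,0.372,3.5,22.4
GLU:CD,0.36,2.1,0.12,0.0,3.5,14.7
GLU:OE1,-0.6,1.6,0.6469,-10.0,6.0,10.8
GLU:OE2,-0.6,1.6,0.6469,-10.0,6.0,10.8
GLY:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
GLY:H,0.25,0.8,0.0498,0.0,3.5,0.0
GLY:CA,0.1,2.235,0.1142,0.372,3.5,22.4
GLY:C,0.55,2.1,0.12,0.0,3.5,14.7
GLY:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
HIS:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
HIS:H,0.25,0.8,0.0498,0.0,3.5,0.0
HIS:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
HIS:C,0.55,2.1,0.12,0.0,3.5,14.7
HIS:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
HIS:CB,0.0,2.235,0.1142,0.372,3.5,22.4
HIS:CG,0.1,2.1,0.12,0.0,3.5,14.7
HIS:ND1,-0.4,1.6,0.2384,-5.95,3.5,4.4
HIS:HD1,0.3,0.8,0.0498,0.0,3.5,0.0
HIS:CD2,0.1,2.1,0.12,0.057,3.5,18.4
HIS:CE1,0.3,2.1,0.12,0.057,3.5,18.4
HIS:NE2,-0.4,1.6,0.2384,-3.82,3.5,4.4
ILE:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
ILE:H,0.25,0.8,0.0498,0.0,3.5,0.0
ILE:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
ILE:C,0.55,2.1,0.12,0.0,3.5,14.7
ILE:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
ILE:CB,0.0,2.365,0.0486,-0.187,3.5,23.7
ILE:CG1,0.0,2.235,0.1142,0.372,3.5,22.4
ILE:CG2,0.0,2.165,0.1811,1.089,3.5,30.0
ILE:CD1,0.0,2.165,0.1811,1.089,3.5,30.0
LEU:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
LEU:H,0.25,0.8,0.0498,0.0,3.5,0.0
LEU:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
LEU:C,0.55,2.1,0.12,0.0,3.5,14.7
LEU:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
LEU:CB,0.0,2.235,0.1142,0.372,3.5,22.4
LEU:CG,0.0,2.365,0.0486,-0.187,3.5,23.7
LEU:CD1,0.0,2.165,0.1811,1.089,3.5,30.0
LEU:CD2,0.0,2.165,0.1811,1.089,3.5,30.0
LYS:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
LYS:H,0.25,0.8,0.0498,0.0,3.5,0.0
LYS:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
LYS:C,0.55,2.1,0.12,0.0,3.5,14.7
LYS:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
LYS:CB,0.0,2.235,0.1142,0.372,3.5,22.4
LYS:CG,0.0,2.235,0.1142,0.372,3.5,22.4
LYS:CD,0.0,2.235,0.1142,0.372,3.5,22.4
LYS:CE,0.25,2.235,0.1142,0.372,3.5,22.4
LYS:NZ,-0.3,1.6,0.2384,-20.0,6.0,11.2
LYS:HZ1,0.35,0.8,0.0498,0.0,3.5,0.0
LYS:HZ2,0.35,0.8,0.0498,0.0,3.5,0.0
LYS:HZ3,0.35,0.8,0.0498,0.0,3.5,0.0
MET:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
MET:H,0.25,0.8,0.0498,0.0,3.5,0.0
MET:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
MET:C,0.55,2.1,0.12,0.0,3.5,14.7
MET:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
MET:CB,0.0,2.235,0.1142,0.372,3.5,22.4
MET:CG,0.06,2.235,0.1142,0.372,3.5,22.4
MET:SD,-0.12,1.89,0.043,-3.24,3.5,14.7
MET:CE,0.06,2.165,0.1811,1.089,3.5,30.0
PHE:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
PHE:H,0.25,0.8,0.0498,0.0,3.5,0.0
PHE:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
PHE:C,0.55,2.1,0.12,0.0,3.5,14.7
PHE:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
PHE:CB,0.0,2.235,0.1142,0.372,3.5,22.4
PHE:CG,0.0,2.1,0.12,0.0,3.5,14.7
PHE:CD1,0.0,2.1,0.12,0.057,3.5,18.4
PHE:CD2,0.0,2.1,0.12,0.057,3.5,18.4
PHE:CE1,0.0,2.1,0.12,0.057,3.5,18.4
PHE:CE2,0.0,2.1,0.12,0.057,3.5,18.4
PHE:CZ,0.0,2.1,0.12,0.057,3.5,18.4
PRO:N,-0.2,1.6,0.2384,-1.0,3.5,4.4
PRO:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
PRO:C,0.55,2.1,0.12,0.0,3.5,14.7
PRO:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
PRO:CB,0.0,2.235,0.1142,0.372,3.5,22.4
PRO:CG,0.0,2.235,0.1142,0.372,3.5,22.4
PRO:CD,0.1,2.235,0.1142,0.372,3.5,22.4
SER:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
SER:H,0.25,0.8,0.0498,0.0,3.5,0.0
SER:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
SER:C,0.55,2.1,0.12,0.0,3.5,14.7
SER:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
SER:CB,0.25,2.235,0.1142,0.372,3.5,22.4
SER:OG,-0.65,1.6,0.1591,-6.7,3.5,10.8
SER:HG,0.4,0.8,0.0498,0.0,3.5,0.0
THR:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
THR:H,0.25,0.8,0.0498,0.0,3.5,0.0
THR:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
THR:C,0.55,2.1,0.12,0.0,3.5,14.7
THR:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
THR:CB,0.25,2.365,0.0486,-0.187,3.5,23.7
THR:OG1,-0.65,1.6,0.1591,-6.7,3.5,10.8
THR:HG1,0.4,0.8,0.0498,0.0,3.5,0.0
THR:CG2,0.0,2.165,0.1811,1.089,3.5,30.0
TRP:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
TRP:H,0.25,0.8,0.0498,0.0,3.5,0.0
TRP:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
TRP:C,0.55,2.1,0.12,0.0,3.5,14.7
TRP:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
TRP:CB,0.0,2.235,0.1142,0.372,3.5,22.4
TRP:CG,0.0,2.1,0.12,0.0,3.5,14.7
TRP:CD1,0.06,2.1,0.12,0.057,3.5,18.4
TRP:CD2,0.0,2.1,0.12,0.0,3.5,14.7
TRP:NE1,-0.36,1.6,0.2384,-5.95,3.5,4.4
TRP:HE1,0.3,0.8,0.0498,0.0,3.5,0.0
TRP:CE2,0.0,2.1,0.12,0.0,3.5,14.7
TRP:CE3,0.0,2.1,0.12,0.057,3.5,18.4
TRP:CZ2,0.0,2.1,0.12,0.057,3.5,18.4
TRP:CZ3,0.0,2.1,0.12,0.057,3.5,18.4
TRP:CH2,0.0,2.1,0.12,0.057,3.5,18.4
TYR:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
TYR:H,0.25,0.8,0.0498,0.0,3.5,0.0
TYR:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
TYR:C,0.55,2.1,0.12,0.0,3.5,14.7
TYR:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
TYR:CB,0.0,2.235,0.1142,0.372,3.5,22.4
TYR:CG,0.0,2.1,0.12,0.0,3.5,14.7
TYR:CD1,0.0,2.1,0.12,0.057,3.5,18.4
TYR:CD2,0.0,2.1,0.12,0.057,3.5,18.4
TYR:CE1,0.0,2.1,0.12,0.057,3.5,18.4
TYR:CE2,0.0,2.1,0.12,0.057,3.5,18.4
TYR:CZ,0.25,2.1,0.12,0.0,3.5,14.7
TYR:OH,-0.65,1.6,0.1591,-6.7,3.5,10.8
TYR:HH,0.4,0.8,0.0498,0.0,3.5,0.0
VAL:N,-0.35,1.6,0.2384,-5.95,3.5,4.4
VAL:H,0.25,0.8,0.0498,0.0,3.5,0.0
VAL:CA,0.1,2.365,0.0486,-0.187,3.5,23.7
VAL:C,0.55,2.1,0.12,0.0,3.5,14.7
VAL:O,-0.55,1.6,0.1591,-5.33,3.5,10.8
VAL:CB,0.0,2.365,0.0486,-0.187,3.5,23.7
VAL:CG1,0.0,2.165,0.1811,1.089,3.5,30.0
VAL:CG2,0.0,2.165,0.1811,1.089,3.5,30.0
ANY:OXT,-0.57,1.6,0.6469,-10.0,6.0,10.8
HOH:O,0.0,1.6,0.1591,0.0,3.5,10.8
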