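aa,chi1,chi2,chi3,chi4,sigma
ARG,-65.0,180.0,180.0,180.0,9.0
ARG,-65.0,180.0,180.0,85.0,9.0
ARG,-65.0,180.0,-65.0,180.0,9.0
ARG,-65.0,180.0,-65.0,85.0,9.0
ARG,-65.0,65.0,180.0,180.0,9.0
ARG,-65.0,65.0,180.0,85.0,9.0
ARG,-65.0,65.0,-65.0,180.0,9.0
ARG,-65.0,65.0,-65.0,85.0,9.0
ARG,180.0,180.0,180.0,180.0,9.0
ARG,180.0,180.0,180.0,85.0,9.0
ARG,180.0,180.0,-65.0,180.0,9.0
ARG,180.0,180.0,-65.0,85.0,9.0
ARG,180.0,65.0,180.0,180.0,9.0
ARG,180.0,65.0,180.0,85.0,9.0
ARG,180.0,65.0,-65.0,180.0,9.0
ARG,180.0,65.0,-65.0,85.0,9.0
ASN,-65.0,-75.0,,,9.0
ASN,-65.0,-20.0,,,9.0
ASN,-65.0,30.0,,,9.0
ASN,-65.0,90.0,,,9.0
ASN,-65.0,150.0,,,9.0
ASN,180.0,-75.0,,,9.0
ASN,180.0,-20.0,,,9.0
ASN,180.0,30.0,,,9.0
ASN,180.0,90.0,,,9.0
ASN,180.0,150.0,,,9.0
ASN,62.0,-75.0,,,9.0
ASN,62.0,-20.0,,,9.0
ASN,62.0,30.0,,,9.0
ASN,62.0,90.0,,,9.0
ASN,62.0,150.0,,,9.0
ASP,-65.0,-30.0,,,9.0
ASP,-65.0,30.0,,,9.0
ASP,-65.0,90.0,,,9.0
ASP,180.0,-30.0,,,9.0
ASP,180.0,30.0,,,9.0
ASP,180.0,90.0,,,9.0
ASP,62.0,-30.0,,,9.0
ASP,62.0,30.0,,,9.0
ASP,62.0,90.0,,,9.0
CYS,-65.0,,,,9.0
CYS,180.0,,,,9.0
CYS,62.0,,,,9.0
GLN,-65.0,-65.0,-90.0,,9.0
GLN,-65.0,-65.0,0.0,,9.0
GLN,-65.0,-65.0,90.0,,9.0
GLN,-65.0,180.0,-90.0,,9.0
GLN,-65.0,180.0,0.0,,9.0
GLN,-65.0,180.0,90.0,,9.0
GLN,-65.0,65.0,-90.0,,9.0
GLN,-65.0,65.0,0.0,,9.0
GLN,-65.0,65.0,90.0,,9.0
GLN,180.0,-65.0,-90.0,,9.0
GLN,180.0,-65.0,0.0,,9.0
GLN,180.0,-65.0,90.0,,9.0
GLN,180.0,180.0,-90.0,,9.0
GLN,180.0,180.0,0.0,,9.0
GLN,180.0,180.0,90.0,,9.0
GLN,180.0,65.0,-90.0,,9.0
GLN,180.0,65.0,0.0,,9.0
GLN,180.0,65.0,90.0,,9.0
GLN,62.0,-65.0,-90.0,,9.0
GLN,62.0,-65.0,0.0,,9.0
GLN,62.0,-65.0,90.0,,9.0
GLN,62.0,180.0,-90.0,,9.0
GLN,62.0,180.0,0.0,,9.0
GLN,62.0,180.0,90.0,,9.0
GLN,62.0,65.0,-90.0,,9.0
GLN,62.0,65.0,0.0,,9.0
GLN,62.0,65.0,90.0,,9.0
GLU,-65.0,-65.0,-30.0,,9.0
GLU,-65.0,-65.0,30.0,,9.0
GLU,-65.0,-65.0,90.0,,9.0
GLU,-65.0,180.0,-30.0,,9.0
GLU,-65.0,180.0,30.0,,9.0
GLU,-65.0,180.0,90.0,,9.0
GLU,-65.0,65.0,-30.0,,9.0
GLU,-65.0,65.0,30.0,,9.0
GLU,-65.0,65.0,90.0,,9.0
GLU,180.0,-65.0,-30.0,,9.0
GLU,180.0,-65.0,30.0,,9.0
GLU,180.0,-65.0,90.0,,9.0
GLU,180.0,180.0,-30.0,,9.0
GLU,180.0,180.0,30.0,,9.0
GLU,180.0,180.0,90.0,,9.0
GLU,180.0,65.0,-30.0,,9.0
GLU,180.0,65.0,30.0,,9.0
GLU,180.0,65.0,90.0,,9.0
GLU,62.0,-65.0,-30.0,,9.0
GLU,62.0,-65.0,30.0,,9.0
GLU,62.0,-65.0,90.0,,9.0
GLU,62.0,180.0,-30.0,,9.0
GLU,62.0,180.0,30.0,,9.0
GLU,62.0,180.0,90.0,,9.0
GLU,62.0,65.0,-30.0,,9.0
GLU,62.0,65.0,30.0,,9.0
GLU,62.0,65.0,90.0,,9.0
HIS,-65.0,90.0,,,9.0
HIS,-65.0,0.0,,,9.0
HIS,-65.0,-75.0,,,9.0
HIS,180.0,90.0,,,9.0
HIS,180.0,0.0,,,9.0
HIS,180.0,-75.0,,,9.0
HIS,62.0,90.0,,,9.0
HIS,62.0,0.0,,,9.0
HIS,62.0,-75.0,,,9.0
ILE,-65.0,170.0,,,9.0
ILE,-65.0,-60.0,,,9.0
ILE,-57.0,100.0,,,9.0
ILE,180.0,165.0,,,9.0
ILE,62.0,170.0,,,9.0
LEU,-65.0,175.0,,,9.0
LEU,180.0,65.0,,,9.0
LEU,-85.0,65.0,,,9.0
LEU,180.0,180.0,,,9.0
LYS,-65.0,180.0,180.0,180.0,9.0
LYS,-65.0,180.0,-65.0,180.0,9.0
LYS,-65.0,65.0,180.0,180.0,9.0
LYS,-65.0,65.0,-65.0,180.0,9.0
LYS,180.0,180.0,180.0,180.0,9.0
LYS,180.0,180.0,-65.0,180.0,9.0
LYS,180.0,65.0,180.0,180.0,9.0
LYS,180.0,65.0,-65.0,180.0,9.0
MET,-65.0,-65.0,-75.0,,9.0
MET,-65.0,-65.0,75.0,,9.0
MET,-65.0,-65.0,180.0,,9.0
MET,-65.0,180.0,-75.0,,9.0
MET,-65.0,180.0,75.0,,9.0
MET,-65.0,180.0,180.0,,9.0
MET,-65.0,65.0,-75.0,,9.0
MET,-65.0,65.0,75.0,,9.0
MET,-65.0,65.0,180.0,,9.0
MET,180.0,-65.0,-75.0,,9.0
MET,180.0,-65.0,75.0,,9.0
MET,180.0,-65.0,180.0,,9.0
MET,180.0,180.0,-75.0,,9.0
MET,180.0,180.0,75.0,,9.0
MET,180.0,180.0,180.0,,9.0
MET,180.0,65.0,-75.0,,9.0
MET,180.0,65.0,75.0,,9.0
MET,180.0,65.0,180.0,,9.0
MET,62.0,-65.0,-75.0,,9.0
MET,62.0,-65.0,75.0,,9.0
MET,62.0,-65.0,180.0,,9.0
MET,62.0,180.0,-75.0,,9.0
MET,62.0,180.0,75.0,,9.0
MET,62.0,180.0,180.0,,9.0
MET,62.0,65.0,-75.0,,9.0
MET,62.0,65.0,75.0,,9.0
MET,62.0,65.0,180.0,,9.0
PHE,-65.0,90.0,,,9.0
PHE,-65.0,45.0,,,9.0
PHE,-65.0,0.0,,,9.0
PHE,-65.0,-45.0,,,9.0
PHE,180.0,90.0,,,9.0
PHE,180.0,45.0,,,9.0
PHE,180.0,0.0,,,9.0
PHE,180.0,-45.0,,,9.0
PHE,62.0,90.0,,,9.0
PHE,62.0,45.0,,,9.0
PHE,62.0,0.0,,,9.0
PHE,62.0,-45.0,,,9.0
SER,-65.0,,,,9.0
SER,180.0,,,,9.0
SER,62.0,,,,9.0
THR,-65.0,,,,9.0
THR,180.0,,,,9.0
THR,62.0,,,,9.0
TRP,-65.0,95.0,,,9.0
TRP,-65.0,0.0,,,9.0
TRP,-65.0,-90.0,,,9.0
TRP,180.0,95.0,,,9.0
TRP,180.0,0.0,,,9.0
TRP,180.0,-90.0,,,9.0
TRP,62.0,95.0,,,9.0
TRP,62.0,0.0,,,9.0
TRP,62.0,-90.0,,,9.0
TYR,-65.0,90.0,,,9.0
TYR,-65.0,45.0,,,9.0
TYR,-65.0,0.0,,,9.0
TYR,-65.0,-45.0,,,9.0
TYR,180.0,90.0,,,9.0
TYR,180.0,45.0,,,9.0
TYR,180.0,0.0,,,9.0
TYR,180.0,-45.0,,,9.0
TYR,62.0,90.0,,,9.0
TYR,62.0,45.0,,,9.0
TYR,62.0,0.0,,,9.0
TYR,62.0,-45.0,,,9.0
VAL,175.0,,,,9.0
VAL,-60.0,,,,9.0
VAL,64.0,,,,9.0
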