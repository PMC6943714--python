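residue,atom,type,charge
ALA,N,N,-0.2
ALA,CA,CT,0.1
ALA,C,C,0.5
ALA,O,O,-0.4
ALA,OXT,O2,-0.4
ALA,CB,CT,0.0
ARG,N,N,-0.2
ARG,CA,CT,0.1
ARG,C,C,0.5
ARG,O,O,-0.4
ARG,OXT,O2,-0.4
ARG,CB,CT,0.0
ARG,CD,CT,0.1
ARG,CG,CT,0.0
ARG,CZ,C,0.5
ARG,NE,N2,0.1
ARG,NH1,N2,0.15
ARG,NH2,N2,0.15
ASN,N,N,-0.2
ASN,CA,CT,0.1
ASN,C,C,0.5
ASN,O,O,-0.4
ASN,OXT,O2,-0.4
ASN,CB,CT,0.0
ASN,CG,C,0.5
ASN,ND2,N,-0.1
ASN,OD1,O,-0.4
ASP,N,N,-0.2
ASP,CA,CT,0.1
ASP,C,C,0.5
ASP,O,O,-0.4
ASP,OXT,O2,-0.4
ASP,CB,CT,0.0
ASP,CG,C,0.4
ASP,OD1,O2,-0.7
ASP,OD2,O2,-0.7
CBA,N,N,-0.2
CBA,CA,CT,0.1
CBA,C,C,0.5
CBA,O,O,-0.4
CBA,OXT,O2,-0.4
CBA,CB,CT,0.0
CBA,CD1,CT,0.0
CBA,CD2,CT,0.0
CBA,CE,CT,0.0
CBA,CG,CT,0.0
CYS,N,N,-0.2
CYS,CA,CT,0.1
CYS,C,C,0.5
CYS,O,O,-0.4
CYS,OXT,O2,-0.4
CYS,CB,CT,0.1
CYS,SG,S,-0.1
GLN,N,N,-0.2
GLN,CA,CT,0.1
GLN,C,C,0.5
GLN,O,O,-0.4
GLN,OXT,O2,-0.4
GLN,CB,CT,0.0
GLN,CD,C,0.5
GLN,CG,CT,0.0
GLN,NE2,N,-0.1
GLN,OE1,O,-0.4
GLU,N,N,-0.2
GLU,CA,CT,0.1
GLU,C,C,0.5
GLU,O,O,-0.4
GLU,OXT,O2,-0.4
GLU,CB,CT,0.0
GLU,CD,C,0.4
GLU,CG,CT,0.0
GLU,OE1,O2,-0.7
GLU,OE2,O2,-0.7
GLY,N,N,-0.2
GLY,CA,CT,0.1
GLY,C,C,0.5
GLY,O,O,-0.4
GLY,OXT,O2,-0.4
HIS,N,N,-0.2
HIS,CA,CT,0.1
HIS,C,C,0.5
HIS,O,O,-0.4
HIS,OXT,O2,-0.4
HIS,CB,CT,0.0
HIS,CD2,CA_AROM,0.0
HIS,CE1,CA_AROM,0.3
HIS,CG,CA_AROM,0.1
HIS,ND1,N,-0.3
HIS,NE2,N,-0.1
ILE,N,N,-0.2
ILE,CA,CT,0.1
ILE,C,C,0.5
ILE,O,O,-0.4
ILE,OXT,O2,-0.4
ILE,CB,CT,0.0
ILE,CD1,CT,0.0
ILE,CG1,CT,0.0
ILE,CG2,CT,0.0
LEU,N,N,-0.2
LEU,CA,CT,0.1
LEU,C,C,0.5
LEU,O,O,-0.4
LEU,OXT,O2,-0.4
LEU,CB,CT,0.0
LEU,CD1,CT,0.0
LEU,CD2,CT,0.0
LEU,CG,CT,0.0
LYS,N,N,-0.2
LYS,CA,CT,0.1
LYS,C,C,0.5
LYS,O,O,-0.4
LYS,OXT,O2,-0.4
LYS,CB,CT,0.0
LYS,CD,CT,0.0
LYS,CE,CT,0.3
LYS,CG,CT,0.0
LYS,NZ,N3,0.7
MET,N,N,-0.2
MET,CA,CT,0.1
MET,C,C,0.5
MET,O,O,-0.4
MET,OXT,O2,-0.4
MET,CB,CT,0.0
MET,CE,CT,0.0
MET,CG,CT,0.0
MET,SD,S,0.0
PHE,N,N,-0.2
PHE,CA,CT,0.1
PHE,C,C,0.5
PHE,O,O,-0.4
PHE,OXT,O2,-0.4
PHE,CB,CT,0.0
PHE,CD1,CA_AROM,0.0
PHE,CD2,CA_AROM,0.0
PHE,CE1,CA_AROM,0.0
PHE,CE2,CA_AROM,0.0
PHE,CG,CA_AROM,0.0
PHE,CZ,CA_AROM,0.0
PRO,N,N,-0.2
PRO,CA,CT,0.1
PRO,C,C,0.5
PRO,O,O,-0.4
PRO,OXT,O2,-0.4
PRO,CB,CT,0.0
PRO,CD,CT,0.0
PRO,CG,CT,0.0
R8A,N,N,-0.2
R8A,CA,CT,0.1
R8A,C,C,0.5
R8A,O,O,-0.4
R8A,OXT,O2,-0.4
R8A,CB,CT,0.0
R8A,CD,CT,0.0
R8A,CE,CT,0.0
R8A,CF,CT,0.0
R8A,CG,CT,0.0
R8A,CH,CT,0.0
R8A,CI,CT,0.0
R8A,CJ,CT,0.0
R8A,CM,CT,0.0
S5A,N,N,-0.2
S5A,CA,CT,0.1
S5A,C,C,0.5
S5A,O,O,-0.4
S5A,OXT,O2,-0.4
S5A,CB,CT,0.0
S5A,CD,CT,0.0
S5A,CE,CT,0.0
S5A,CF,CT,0.0
S5A,CG,CT,0.0
S5A,CM,CT,0.0
SER,N,N,-0.2
SER,CA,CT,0.1
SER,C,C,0.5
SER,O,O,-0.4
SER,OXT,O2,-0.4
SER,CB,CT,0.25
SER,OG,OH,-0.25
THR,N,N,-0.2
THR,CA,CT,0.1
THR,C,C,0.5
THR,O,O,-0.4
THR,OXT,O2,-0.4
THR,CB,CT,0.25
THR,CG2,CT,0.0
THR,OG1,OH,-0.25
TRP,N,N,-0.2
TRP,CA,CT,0.1
TRP,C,C,0.5
TRP,O,O,-0.4
TRP,OXT,O2,-0.4
TRP,CB,CT,0.0
TRP,CD1,CA_AROM,0.05
TRP,CD2,CA_AROM,0.0
TRP,CE2,CA_AROM,0.05
TRP,CE3,CA_AROM,0.0
TRP,CG,CA_AROM,0.0
TRP,CH2,CA_AROM,0.0
TRP,CZ2,CA_AROM,0.0
TRP,CZ3,CA_AROM,0.0
TRP,NE1,N,-0.1
TYR,N,N,-0.2
TYR,CA,CT,0.1
TYR,C,C,0.5
TYR,O,O,-0.4
TYR,OXT,O2,-0.4
TYR,CB,CT,0.0
TYR,CD1,CA_AROM,0.0
TYR,CD2,CA_AROM,0.0
TYR,CE1,CA_AROM,0.0
TYR,CE2,CA_AROM,0.0
TYR,CG,CA_AROM,0.0
TYR,CZ,CA_AROM,0.25
TYR,OH,OH,-0.25
VAL,N,N,-0.2
VAL,CA,CT,0.1
VAL,C,C,0.5
VAL,O,O,-0.4
VAL,OXT,O2,-0.4
VAL,CB,CT,0.0
VAL,CG1,CT,0.0
VAL,CG2,CT,0.0
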