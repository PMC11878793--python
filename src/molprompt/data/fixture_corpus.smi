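# Curated fixture corpus: one SMILES per line, diverse drug-like and simple
# molecules spanning many scaffolds and functional-group classes.
# Lines starting with '#' are comments.
CC(=O)Oc1ccccc1C(=O)O
CC(=O)Nc1ccc(O)cc1
CC(C)Cc1ccc(cc1)C(C)C(=O)O
Cn1cnc2c1c(=O)n(C)c(=O)n2C
CN1CCCC1c1cccnc1
CCO
CC(C)O
OCC(O)CO
C1CCCCC1
c1ccccc1
Cc1ccccc1
Oc1ccccc1
Nc1ccccc1
Clc1ccccc1
Brc1ccccc1
Ic1ccccc1
Fc1ccccc1
O=C(O)c1ccccc1
OCc1ccccc1
N#Cc1ccccc1
O=[N+]([O-])c1ccccc1
COc1ccccc1
CCOC(=O)c1ccccc1
O=Cc1ccccc1
CC(=O)c1ccccc1
NC(=O)c1ccccc1
c1ccc2ccccc2c1
c1ccc2c(c1)ccc1ccccc12
c1ccncc1
c1ccoc1
c1ccsc1
c1cc[nH]c1
c1cnc[nH]1
c1cscn1
c1ccc2[nH]ccc2c1
c1ccc2ocnc2c1
OC(=O)CC(O)(CC(=O)O)C(=O)O
NCC(=O)O
CC(N)C(=O)O
N[C@@H](Cc1ccccc1)C(=O)O
N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O
N[C@@H](CO)C(=O)O
N[C@@H](CS)C(=O)O
N[C@@H](CCSC)C(=O)O
OC(=O)CCC(=O)O
OC(=O)C=CC(=O)O
OC(=O)CCCCC(=O)O
CCCCCCCCCC(=O)O
CCCCCCCCCCCCCCCC(=O)O
CCCCCCCC=CCCCCCCCC(=O)O
CCCCCO
CCCCCC
CCCCCCCC
CC(C)(C)O
CC(C)(C)c1ccc(O)cc1
CC(=O)OCC
CCOC(=O)CC
CCOCC
CC(=O)NC
CCNCC
CCN(CC)CC
C[N+](C)(C)C
CS(=O)C
CS(=O)(=O)C
CS(=O)(=O)N
NS(=O)(=O)c1ccc(N)cc1
CCSSCC
CCS
SCC(O)CO
C=C
C#C
CC=CC
CC#CC
C=CC=C
CC(C)=CCO
CC1=CC(=O)CC(C)(C)C1
O=C1CCCCC1
O=C1CCCC1
OC1CCCCC1
NC1CCCCC1
C1CCNCC1
C1CCOC1
C1CCOCC1
O1CCOCC1
C1CNCCN1
C1CCNC1
N1CCNCC1
CN1CCNCC1
CN1CCN(CC1)c1ccccc1
O=C1NC(=O)NC(=O)C1
CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O
CC(=O)OC1CC2CCC1(C)C2(C)C
CC12CCC3c4ccc(O)cc4CCC3C1CCC2O
CC(C)CCCC(C)C1CCC2C3CC=C4CC(O)CCC4(C)C3CCC12C
OC(=O)C1CCCCC1
O=C(Nc1ccccc1)c1ccccc1
O=C(Oc1ccccc1)c1ccccc1
c1ccc(-c2ccccc2)cc1
c1ccc(Cc2ccccc2)cc1
c1ccc(Oc2ccccc2)cc1
c1ccc(Sc2ccccc2)cc1
c1ccc(Nc2ccccc2)cc1
O=C(c1ccccc1)c1ccccc1
OCCO
OCCN
NCCN
OCCOCCO
ClCCCl
ClC(Cl)Cl
FC(F)(F)c1ccccc1
FC(F)(F)c1cccc(N)c1
Nc1ccc(Cl)cc1
Nc1ccc(O)cc1
Nc1ccc(C)cc1
Oc1ccc(Cl)cc1
Oc1ccccc1O
Oc1ccccc1C(=O)O
Oc1ccccc1C=O
COc1ccc(C=O)cc1
COc1cc(C=O)ccc1O
CC(=O)Nc1ccccc1
CC(=O)N(C)C
CN(C)C=O
CC#N
CCC#N
CC(=O)C
CCC(C)=O
CC(=O)CC(C)=O
CC(O)CC(C)=O
OCC1OC(O)C(O)C(O)C1O
OCC1OC(OC2C(O)C(O)C(O)OC2CO)C(O)C(O)C1O
Cn1c(=O)c2[nH]cnc2n(C)c1=O
CN1C(=O)N(C)c2ncn(C)c2C1=O
Nc1ncnc2[nH]cnc12
Nc1nc2[nH]cnc2c(=O)[nH]1
Cc1ncc([N+](=O)[O-])n1CCO
OCCn1ccnc1
Clc1ccccc1Cl
Clc1ccc(Cl)cc1
Cc1ccc(C)cc1
Cc1ccccc1C
Cc1cccc(C)c1
CCc1ccccc1
C=Cc1ccccc1
C#Cc1ccccc1
CC(C)c1ccccc1
CC(C)(C)c1ccccc1
CCCCc1ccccc1
OC(c1ccccc1)c1ccccc1
NC(c1ccccc1)c1ccccc1
O=C(O)C(c1ccccc1)c1ccccc1
CC(c1ccccc1)C(=O)O
COC(=O)c1ccccc1C(=O)OC
CCOC(=O)c1ccccc1C(=O)OCC
O=C1OC(=O)c2ccccc21
O=C1NC(=O)c2ccccc21
O=S1(=O)NC(=O)c2ccccc21
CC1CC(=O)NC(=O)C1
CCC1(CC)C(=O)NC(=O)NC1=O
CCC1(c2ccccc2)C(=O)NC(=O)NC1=O
O=C1CN=C(c2ccccc2)c2cc(Cl)ccc2N1
CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21
OC(CCN(C)C)(c1ccccc1)c1ccccc1
CN(C)CCCN1c2ccccc2Sc2ccccc21
CN(C)CCCN1c2ccccc2CCc2ccccc21
Clc1ccc2c(c1)N(CCCN1CCN(CCO)CC1)c1ccccc1S2
CC(CN1c2ccccc2Sc2ccc(Cl)cc21)N(C)C
NC(=O)c1cccnc1
OC(=O)c1cccnc1
Cc1ccncc1
Nc1ccncc1
Oc1ccncc1
c1ccc(cc1)C(=O)NCCN
CCN(CC)CCNC(=O)c1ccc(N)cc1
CCN(CC)CCOC(=O)c1ccc(N)cc1
COC(=O)C1C2CCC(CC1OC(=O)c1ccccc1)N2C
CN1C2CCC1CC(OC(=O)C(CO)c1ccccc1)C2
OCC(N)Cc1ccccc1
ONC(=O)c1ccccc1
O=C(NO)c1ccccc1
NN=Cc1ccccc1
NNc1ccccc1
N=C(N)N
NC(=O)N
NC(=S)N
NC(N)=NC#N
CNC(=N)NCCSCc1nc[nH]c1C
OC(=O)CCCCCCC(=O)O
CCCCN
CCCCCN
NCCCCN
NCCCCCN
NCCCN
CCCCNCCCC
CNC
CN(C)C
NCCO
OCCNCCO
CC(N)CO
OCC(N)(CO)CO
CC(C)NCC(O)COc1ccccc1
CC(C)NCC(O)COc1cccc2ccccc12
CNCC(O)c1ccc(O)c(O)c1
NCC(O)c1ccc(O)c(O)c1
NC(=O)NC1NC(=O)NC1=O
CC(=O)NCCCS(=O)(=O)O
CC(C)(N)Cc1ccccc1
CNC(C)Cc1ccccc1
CC(N)Cc1ccccc1
COc1ccc2cc(ccc2c1)C(C)C(=O)O
Cc1cc(=O)oc2cc(O)ccc12
O=c1ccc2ccccc2o1
O=c1cc(-c2ccccc2)oc2ccccc12
Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O
COc1cc(C=CC(=O)CC(=O)C=Cc2ccc(O)c(OC)c2)ccc1O
CC(=O)CCc1ccc(O)cc1
OCCc1ccc(O)cc1
OC(=O)Cc1ccc(O)cc1
OC(=O)c1cc(O)c(O)c(O)c1
OC(=O)c1ccc(O)cc1
COC(=O)c1ccc(O)cc1
CCOC(=O)c1ccc(N)cc1
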