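# Functional-group definition table: one named SMARTS pattern per row.
# Columns: name <TAB> smarts.  Lines starting with '#' are comments.
# 82 entries; names are unique and every pattern compiles under RDKit.
hydroxyl	[OX2H]
phenol	[OX2H][cX3]
primary_alcohol	[CX4H2][OX2H]
secondary_alcohol	[CX4H1]([#6])[OX2H]
tertiary_alcohol	[CX4]([#6])([#6])([#6])[OX2H]
carbonyl	[CX3]=[OX1]
aldehyde	[CX3H1](=O)[#6]
ketone	[#6][CX3](=O)[#6]
carboxyl	[CX3](=O)[OX2H1]
carboalkoxy	[CX3](=O)[OX2H0][#6]
carbonate	[OX2][CX3](=O)[OX2]
anhydride	[CX3](=O)[OX2][CX3](=O)
ether	[OD2]([#6])[#6]
alkoxy	[OX2][CX4]
aryl_ether	[cX3][OX2][#6]
epoxide	C1OC1
peroxide	[OX2][OX2]
primary_amine	[NX3;H2;!$(NC=O);!$(NS(=O)=O)]
secondary_amine	[NX3;H1;!$(NC=O);!$(NS(=O)=O)]([#6])[#6]
tertiary_amine	[NX3;H0;!$(NC=O);!$(N=O);!$(N[O-])]([#6])([#6])[#6]
quaternary_ammonium	[NX4+]
aromatic_amine	[NX3][cX3]
hydroxylamine	[NX3][OX2H]
amide	[NX3][CX3](=[OX1])
primary_amide	[NX3H2][CX3](=[OX1])
lactam	[NX3;R][CX3;R](=[OX1])
carbamate	[NX3][CX3](=[OX1])[OX2]
urea	[NX3][CX3](=[OX1])[NX3]
guanidine	[NX3][CX3](=[NX2])[NX3]
amidine	[NX3][CX3]=[NX2]
imine	[CX3]=[NX2]
nitrile	[CX2]#[NX1]
isocyanate	[NX2]=[CX2]=[OX1]
isothiocyanate	[NX2]=[CX2]=[SX1]
azide	[NX2]=[NX2+]=[NX1-]
azo	[#6][NX2]=[NX2][#6]
diazonium	[NX2+]#[NX1]
nitro	[$([NX3](=O)=O),$([NX3+](=O)[O-])]
nitroso	[NX2]=[OX1]
nitrate_ester	[OX2][NX3](=[OX1])=[OX1]
hydrazine	[NX3][NX3]
hydrazone	[NX3][NX2]=[CX3]
oxime	[CX3]=[NX2][OX2H]
fluoro	[F]
chloro	[Cl]
bromo	[Br]
iodo	[I]
trifluoromethyl	[CX4](F)(F)F
acyl_halide	[CX3](=[OX1])[F,Cl,Br,I]
thiol	[SX2H]
thioether	[SX2]([#6])[#6]
disulfide	[SX2][SX2]
thiocarbonyl	[CX3]=[SX1]
thioamide	[NX3][CX3]=[SX1]
sulfoxide	[SX3](=[OX1])([#6])[#6]
sulfone	[SX4](=[OX1])(=[OX1])([#6])[#6]
sulfonamide	[SX4](=[OX1])(=[OX1])[NX3]
sulfonic_acid	[SX4](=[OX1])(=[OX1])[OX2H]
sulfonate_ester	[SX4](=[OX1])(=[OX1])[OX2][#6]
phosphine	[PX3]
phosphate	[PX4](=[OX1])([OX2])([OX2])[OX2]
phosphonate	[PX4](=[OX1])([OX2])([OX2])[#6]
phenyl	c1ccccc1
naphthyl	c1ccc2ccccc2c1
pyridyl	c1ccncc1
pyrimidinyl	c1cncnc1
pyrrole	c1cc[nH]c1
imidazole	c1cnc[nH]1
pyrazole	c1cc[nH]n1
furan	c1ccoc1
thiophene	c1ccsc1
oxazole	c1ocnc1
thiazole	c1scnc1
indole	c1ccc2[nH]ccc2c1
alkene	[CX3]=[CX3]
alkyne	[CX2]#[CX2]
allyl	[CX4][CX3]=[CX3]
alkyl	[CX4;!$(C[OX2H]);!$(C=O)]
methyl	[CX4H3]
methylene	[CX4H2]
methine	[CX4H1]
halo_arene	[F,Cl,Br,I][cX3]
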