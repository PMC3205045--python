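benzene	SMILES	c1ccccc1
benzene	INCHI	InChI=1S/C6H6/c1-2-4-6-5-3-1/h1-6H
toluene	SMILES	Cc1ccccc1
toluene	INCHI	InChI=1S/C7H8/c1-7-5-3-2-4-6-7/h2-6H,1H3
ethyl acetate	SMILES	CCOC(C)=O
ethyl acetate	INCHI	InChI=1S/C4H8O2/c1-3-6-4(2)5/h3H2,1-2H3
methanol	SMILES	CO
ethanol	SMILES	CCO
ethanol	INCHI	InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3
isopropanol	SMILES	CC(C)O
acetone	SMILES	CC(C)=O
acetonitrile	SMILES	CC#N
chloroform	SMILES	ClC(Cl)Cl
dichloromethane	SMILES	ClCCl
tetrahydrofuran	SMILES	C1CCOC1
dioxane	SMILES	C1COCCO1
diethyl ether	SMILES	CCOCC
dimethylformamide	SMILES	CN(C)C=O
dimethylsulfoxide	SMILES	CS(C)=O
water	SMILES	O
water	INCHI	InChI=1S/H2O/h1H2
ammonia	SMILES	N
hydrogen peroxide	SMILES	OO
phenol	SMILES	Oc1ccccc1
aniline	SMILES	Nc1ccccc1
pyridine	SMILES	c1ccncc1
furan	SMILES	c1ccoc1
thiophene	SMILES	c1ccsc1
naphthalene	SMILES	c1ccc2ccccc2c1
anthracene	SMILES	c1ccc2cc3ccccc3cc2c1
cyclohexane	SMILES	C1CCCCC1
hexane	SMILES	CCCCCC
pentane	SMILES	CCCCC
styrene	SMILES	C=Cc1ccccc1
benzaldehyde	SMILES	O=Cc1ccccc1
acetaldehyde	SMILES	CC=O
formaldehyde	SMILES	C=O
acetic acid	SMILES	CC(O)=O
formic acid	SMILES	OC=O
benzoic acid	SMILES	OC(=O)c1ccccc1
trifluoroacetic acid	SMILES	OC(=O)C(F)(F)F
triethylamine	SMILES	CCN(CC)CC
piperidine	SMILES	C1CCNCC1
morpholine	SMILES	C1COCCN1
glucose	SMILES	OCC1OC(O)C(O)C(O)C1O
glycine	SMILES	NCC(O)=O
alanine	SMILES	CC(N)C(O)=O
caffeine	SMILES	Cn1cnc2n(C)c(=O)n(C)c(=O)c12
aspirin	SMILES	CC(=O)Oc1ccccc1C(O)=O
ibuprofen	SMILES	CC(C)Cc1ccc(cc1)C(C)C(O)=O
sodium chloride	SMILES	[Na+].[Cl-]
sodium hydroxide	SMILES	[Na+].[OH-]
potassium carbonate	SMILES	[K+].[K+].[O-]C([O-])=O
magnesium sulfate	SMILES	[Mg++].[O-]S([O-])(=O)=O
ferrocene	SMILES	[Fe].c1cccc1.c1cccc1
benzene	CML	<molecule id="benzene"><formula concise="C 6 H 6"/></molecule>
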