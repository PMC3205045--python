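ethyl acetate	FIX:0000001
acetate	FIX:0000002
benzene	FIX:0000003
toluene	FIX:0000004
methanol	FIX:0000005
ethanol	FIX:0000006
acetone	FIX:0000007
chloroform	FIX:0000008
dichloromethane	FIX:0000009
tetrahydrofuran	FIX:0000010
acetonitrile	FIX:0000011
diethyl ether	FIX:0000012
water	FIX:0000013
sodium chloride	FIX:0000014
sodium hydroxide	FIX:0000015
hydrochloric acid	FIX:0000016
sulfuric acid	FIX:0000017
acetic acid	FIX:0000018
formic acid	FIX:0000019
nitric acid	FIX:0000020
carbon dioxide	FIX:0000021
carbon monoxide	FIX:0000022
hydrogen peroxide	FIX:0000023
ammonium chloride	FIX:0000024
potassium carbonate	FIX:0000025
sodium bicarbonate	FIX:0000026
magnesium sulfate	FIX:0000027
sodium sulfate	FIX:0000028
alcohol	FIX:0000029
aldehyde	FIX:0000030
ketone	FIX:0000031
ester	FIX:0000032
ether	FIX:0000033
amine	FIX:0000034
amide	FIX:0000035
alkane	FIX:0000036
alkene	FIX:0000037
alkyne	FIX:0000038
arene	FIX:0000039
halide	FIX:0000040
carboxylic acid	FIX:0000041
mass spectrometry	FIX:0000100
mass spectrometry	FIX:0000101
nuclear magnetic resonance	FIX:0000102
infrared spectroscopy	FIX:0000103
ultraviolet spectroscopy	FIX:0000104
x-ray diffraction	FIX:0000105
gas chromatography	FIX:0000106
liquid chromatography	FIX:0000107
thin layer chromatography	FIX:0000108
column chromatography	FIX:0000109
recrystallization	FIX:0000110
distillation	FIX:0000111
sublimation	FIX:0000112
titration	FIX:0000113
elemental analysis	FIX:0000114
melting point	FIX:0000115
boiling point	FIX:0000116
oxidation	REX:0000001
reduction	REX:0000002
hydrolysis	REX:0000003
hydrogenation	REX:0000004
dehydrogenation	REX:0000005
halogenation	REX:0000006
chlorination	REX:0000007
bromination	REX:0000008
nitration	REX:0000009
sulfonation	REX:0000010
alkylation	REX:0000011
acylation	REX:0000012
methylation	REX:0000013
esterification	REX:0000014
saponification	REX:0000015
polymerization	REX:0000016
isomerization	REX:0000017
cyclization	REX:0000018
condensation	REX:0000019
substitution	REX:0000020
elimination	REX:0000021
addition reaction	REX:0000022
rearrangement	REX:0000023
decarboxylation	REX:0000024
dehydration	REX:0000025
epoxidation	REX:0000026
ozonolysis	REX:0000027
transesterification	REX:0000028
amination	REX:0000029
carbonylation	REX:0000030
cycloaddition	REX:0000031
metathesis	REX:0000032
solvent	CHEB:0000001
catalyst	CHEB:0000002
reagent	CHEB:0000003
electrophile	CHEB:0000004
nucleophile	CHEB:0000005
oxidant	CHEB:0000006
reductant	CHEB:0000007
ligand	CHEB:0000008
monomer	CHEB:0000009
polymer	CHEB:0000010
isotope	CHEB:0000011
ion	CHEB:0000012
cation	CHEB:0000013
anion	CHEB:0000014
radical	CHEB:0000015
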