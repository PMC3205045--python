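benzene
toluene
xylene
phenol
aniline
pyridine
pyrimidine
pyrrole
furan
thiophene
imidazole
indole
quinoline
naphthalene
anthracene
methane
ethane
propane
butane
pentane
hexane
heptane
octane
cyclohexane
cyclopentane
methanol
ethanol
propanol
butanol
isopropanol
glycerol
phenylalanine
cholesterol
menthol
ethylene
propylene
acetylene
styrene
isoprene
butadiene
methyl
ethyl
propyl
butyl
isopropyl
phenyl
benzyl
vinyl
allyl
acetyl
formyl
hydroxyl
carbonyl
carboxyl
tosyl
mesyl
acetate
formate
benzoate
sulfate
sulfonate
nitrate
nitrite
phosphate
carbonate
bicarbonate
citrate
tartrate
oxalate
malonate
succinate
fumarate
lactate
pyruvate
chloride
bromide
iodide
fluoride
hydroxide
oxide
peroxide
sulfide
nitride
hydride
cyanide
azide
amide
imide
anhydride
chlorobenzene
bromobenzene
nitrobenzene
benzaldehyde
acetaldehyde
formaldehyde
acetone
butanone
cyclohexanone
benzophenone
acetonitrile
benzonitrile
chloroform
dichloromethane
tetrahydrofuran
dioxane
dimethylformamide
dimethylsulfoxide
triethylamine
diisopropylamine
morpholine
piperidine
pyrrolidine
ammonia
hydrazine
glucose
fructose
sucrose
lactose
ribose
glycine
alanine
serine
cysteine
lysine
arginine
histidine
tyrosine
tryptophan
adenine
guanine
cytosine
thymine
uracil
caffeine
nicotine
morphine
quinine
aspirin
ibuprofen
paracetamol
penicillin
sodium
potassium
lithium
magnesium
calcium
aluminium
titanium
chromium
manganese
cobalt
nickel
copper
zinc
palladium
platinum
ruthenium
rhodium
iridium
osmium
tungsten
molybdenum
vanadium
borane
silane
phosphine
sulfoxide
sulfone
ester
ether
ketone
aldehyde
alkane
alkene
alkyne
alcohol
amine
ketal
acetal
lactone
lactam
epoxide
carbene
ylide
enolate
enamine
imine
oxime
hydrazone
carbamate
urethane
isocyanate
thiol
disulfide
porphyrin
ferrocene
fullerene
dichlorobenzylamine
trifluoroacetic
methanesulfonic
toluenesulfonic
hydrochloric
sulfuric
nitric
phosphoric
acetic
formic
benzoic
citric
oxalic
salicylic
stearic
palmitic
oleic
linoleic
ascorbic
folic
glutamic
aspartic
butyllithium
diethylzinc
trimethylsilyl
tetrabutylammonium
borohydride
permanganate
dichromate
periodate
persulfate
thiosulfate
hypochlorite
triphenylphosphine
dibenzylideneacetone
acetylacetonate
ethylenediamine
bipyridine
phenanthroline
terpyridine
crotonaldehyde
cinnamaldehyde
furfural
vanillin
anisole
veratrole
catechol
resorcinol
hydroquinone
cresol
guaiacol
eugenol
limonene
pinene
camphor
borneol
geraniol
citral
carvone
thymol
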