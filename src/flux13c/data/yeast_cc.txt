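# Yeast central carbon metabolism, atom-mapped.
#
# Carbon indices are 1-based from the most-oxidized end (C1 of glucose is
# the aldehyde carbon).  CO2 and the one-carbon (methylene-THF) pool c1u are
# unbalanced: they act as fixed-labeling sources/sinks.  Cofactor terms are
# annotations only and are never mass-balanced.  Succinate/fumarate symmetry
# is expressed as two half-weight atom-map variants of SDH.  The glyoxylate
# shunt is not part of this model (repressed under the glucose-limited
# conditions the model describes).
#
# reactions: 49
#
# METABOLITES
# id  name  compartment  nC  balanced
glc_ext   glucose                        extracellular   6   no
co2       carbon-dioxide                 cytosol         1   no
c1u       methylene-THF-one-carbon      cytosol         1   no
biomass   biomass                        extracellular   0   no
glyc_ext  glycerol-external              extracellular   3   no
etoh_ext  ethanol-external               extracellular   2   no
acc_ext   acetate-external               extracellular   2   no
pyr_ext   pyruvate-external              extracellular   3   no
g6p       glucose-6-phosphate            cytosol         6   yes
f6p       fructose-6-phosphate           cytosol         6   yes
fdp       fructose-1,6-bisphosphate      cytosol         6   yes
dhap      dihydroxyacetone-phosphate     cytosol         3   yes
g3p       glyceraldehyde-3-phosphate     cytosol         3   yes
glyc3p    glycerol-3-phosphate           cytosol         3   yes
glyc      glycerol                       cytosol         3   yes
13dpg     1,3-bisphosphoglycerate        cytosol         3   yes
3pg       3-phosphoglycerate             cytosol         3   yes
2pg       2-phosphoglycerate             cytosol         3   yes
pep       phosphoenolpyruvate            cytosol         3   yes
pyr       pyruvate                       cytosol         3   yes
6pgl      6-phospho-glucono-lactone      cytosol         6   yes
6pgc      6-phospho-gluconate            cytosol         6   yes
ru5p      ribulose-5-phosphate           cytosol         5   yes
xu5p      xylulose-5-phosphate           cytosol         5   yes
r5p       ribose-5-phosphate             cytosol         5   yes
s7p       sedoheptulose-7-phosphate      cytosol         7   yes
e4p       erythrose-4-phosphate          cytosol         4   yes
ser       serine                         cytosol         3   yes
gly       glycine                        cytosol         2   yes
thr       threonine                      cytosol         4   yes
acald     acetaldehyde                   cytosol         2   yes
etoh      ethanol                        cytosol         2   yes
acc       acetate                        cytosol         2   yes
accoa     acetyl-CoA                     cytosol         2   yes
pyr_m     pyruvate-mitochondrial         mitochondrion   3   yes
accoa_m   acetyl-CoA-mitochondrial       mitochondrion   2   yes
oaa       oxaloacetate                   cytosol         4   yes
oaa_m     oxaloacetate-mitochondrial     mitochondrion   4   yes
cit       citrate                        mitochondrion   6   yes
icit      isocitrate                     mitochondrion   6   yes
akg       alpha-ketoglutarate            mitochondrion   5   yes
succoa    succinyl-CoA                   mitochondrion   4   yes
succ      succinate                      mitochondrion   4   yes
fum       fumarate                       mitochondrion   4   yes
mal       malate                         mitochondrion   4   yes
#
# REACTIONS
GLK   : 1 glc_ext -> 1 g6p | irr | cofactors ATP:-1 | map glc_ext#abcdef -> g6p#abcdef
PGI   : 1 g6p -> 1 f6p | rev | map g6p#abcdef -> f6p#abcdef
PFK   : 1 f6p -> 1 fdp | irr | cofactors ATP:-1 | map f6p#abcdef -> fdp#abcdef
FBA   : 1 fdp -> 1 dhap + 1 g3p | rev | map fdp#abcdef -> dhap#abc + g3p#def
TPI   : 1 dhap -> 1 g3p | rev | map dhap#abc -> g3p#cba
GPD   : 1 dhap -> 1 glyc3p | irr | cofactors NADH:-1 | map dhap#abc -> glyc3p#abc
GPP   : 1 glyc3p -> 1 glyc | irr | map glyc3p#abc -> glyc#abc
GLYX  : 1 glyc -> 1 glyc_ext | irr | map glyc#abc -> glyc_ext#abc
GAPD  : 1 g3p -> 1 13dpg | rev | cofactors NADH:1 | map g3p#abc -> 13dpg#abc
PGK   : 1 13dpg -> 1 3pg | rev | cofactors ATP:1 | map 13dpg#abc -> 3pg#abc
PGM   : 1 3pg -> 1 2pg | rev | map 3pg#abc -> 2pg#abc
ENO   : 1 2pg -> 1 pep | rev | map 2pg#abc -> pep#abc
PYK   : 1 pep -> 1 pyr | irr | cofactors ATP:1 | map pep#abc -> pyr#abc
ZWF   : 1 g6p -> 1 6pgl | irr | cofactors NADPH:1 | map g6p#abcdef -> 6pgl#abcdef
SOL   : 1 6pgl -> 1 6pgc | irr | map 6pgl#abcdef -> 6pgc#abcdef
GND   : 1 6pgc -> 1 ru5p + 1 co2 | irr | cofactors NADPH:1 | map 6pgc#abcdef -> co2#a + ru5p#bcdef
RPE   : 1 ru5p -> 1 xu5p | rev | map ru5p#abcde -> xu5p#abcde
RPI   : 1 ru5p -> 1 r5p | rev | map ru5p#abcde -> r5p#abcde
TKL1  : 1 xu5p + 1 r5p -> 1 s7p + 1 g3p | rev | map xu5p#abcde + r5p#fghij -> s7p#abfghij + g3p#cde
TAL   : 1 s7p + 1 g3p -> 1 e4p + 1 f6p | rev | map s7p#abcdefg + g3p#hij -> e4p#defg + f6p#abchij
TKL2  : 1 xu5p + 1 e4p -> 1 f6p + 1 g3p | rev | map xu5p#abcde + e4p#fghi -> f6p#abfghi + g3p#cde
SERS  : 1 3pg -> 1 ser | irr | map 3pg#abc -> ser#abc
SHMF  : 1 ser -> 1 gly + 1 c1u | irr | map ser#abc -> gly#ab + c1u#c
SHMR  : 1 gly + 1 c1u -> 1 ser | irr | map gly#ab + c1u#c -> ser#abc
THRS  : 1 oaa -> 1 thr | irr | cofactors NADPH:-2 ATP:-2 | map oaa#abcd -> thr#abcd
GLYT  : 1 thr -> 1 gly + 1 acald | irr | map thr#abcd -> gly#ab + acald#cd
PDC   : 1 pyr -> 1 acald + 1 co2 | irr | map pyr#abc -> co2#a + acald#bc
ADH   : 1 acald -> 1 etoh | rev | cofactors NADH:-1 | map acald#ab -> etoh#ab
ETOHX : 1 etoh -> 1 etoh_ext | irr | map etoh#ab -> etoh_ext#ab
ALD   : 1 acald -> 1 acc | irr | cofactors NADPH:1 | map acald#ab -> acc#ab
ACCX  : 1 acc -> 1 acc_ext | irr | map acc#ab -> acc_ext#ab
ACS   : 1 acc -> 1 accoa | irr | cofactors ATP:-2 | map acc#ab -> accoa#ab
PYRX  : 1 pyr -> 1 pyr_ext | irr | map pyr#abc -> pyr_ext#abc
PYT   : 1 pyr -> 1 pyr_m | irr | map pyr#abc -> pyr_m#abc
PDH   : 1 pyr_m -> 1 accoa_m + 1 co2 | irr | cofactors NADH:1 | map pyr_m#abc -> co2#a + accoa_m#bc
CS    : 1 oaa_m + 1 accoa_m -> 1 cit | irr | map accoa_m#ab + oaa_m#cdef -> cit#abdefc
ACO   : 1 cit -> 1 icit | rev | map cit#abcdef -> icit#abcdef
IDH   : 1 icit -> 1 akg + 1 co2 | irr | cofactors NADPH:1 | map icit#abcdef -> akg#edcba + co2#f
KGD   : 1 akg -> 1 succoa + 1 co2 | irr | cofactors NADH:1 | map akg#abcde -> co2#a + succoa#bcde
SCS   : 1 succoa -> 1 succ | irr | cofactors ATP:1 | map succoa#abcd -> succ#abcd
SDH   : 1 succ -> 1 fum | irr | cofactors FADH2:1 | map succ#abcd -> fum#abcd @0.5 ; succ#abcd -> fum#dcba @0.5
FUMR  : 1 fum -> 1 mal | rev | map fum#abcd -> mal#abcd
MDH   : 1 mal -> 1 oaa_m | rev | cofactors NADH:1 | map mal#abcd -> oaa_m#abcd
PYC   : 1 pyr + 1 co2 -> 1 oaa | irr | cofactors ATP:-1 | map pyr#abc + co2#d -> oaa#abcd
OAT1  : 1 oaa -> 1 oaa_m | irr | map oaa#abcd -> oaa_m#abcd
OAT2  : 1 oaa_m -> 1 oaa | irr | map oaa_m#abcd -> oaa#abcd
PCK   : 1 oaa -> 1 pep + 1 co2 | irr | cofactors ATP:-1 | map oaa#abcd -> pep#abc + co2#d
MAE   : 1 mal -> 1 pyr_m + 1 co2 | irr | cofactors NADPH:1 | map mal#abcd -> pyr_m#abc + co2#d
BIO   : 1.20 g6p + 0.38 r5p + 0.30 e4p + 0.05 g3p + 0.40 3pg + 0.55 pep + 1.00 pyr + 0.80 pyr_m + 1.20 accoa + 0.60 oaa + 0.25 thr + 0.30 ser + 0.45 gly + 0.25 c1u + 1.00 akg -> 1 biomass | irr | sink
#
# BIOMASS
biomass_reaction: BIO
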