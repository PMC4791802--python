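# TBDMS amino-acid fragments mapped onto their biosynthetic precursor pools.
# Amino acids inherit the labeling of their precursors: Ala <- mitochondrial
# pyruvate, Asp <- mitochondrial oxaloacetate, Glu <- alpha-ketoglutarate,
# Ser <- 3PG-derived serine, Gly <- serine C1-C2, Thr <- cytosolic
# oxaloacetate (via the threonine pool), Val C1-C2 <- cytosolic pyruvate,
# Phe C1-C2 <- PEP.  [M-57] retains all skeleton carbons, [M-85] loses C1
# (with one O), f302 retains C1-C2.  The formula column lists the ion's
# atoms EXCLUDING the retained skeleton carbons.
# amino_acid	fragment	precursor	retained_carbons	formula
Ala	Ala_M57	pyr_m	1,2,3	C8H26NO2Si2
Ala	Ala_M85	pyr_m	2,3	C8H26NO1Si2
Ala	Ala_f302	pyr_m	1,2	C8H22NO2Si2
Gly	Gly_M57	gly	1,2	C8H24NO2Si2
Gly	Gly_M85	gly	2	C8H24NO1Si2
Ser	Ser_M57	ser	1,2,3	C14H40NO3Si3
Ser	Ser_M85	ser	2,3	C14H40NO2Si3
Ser	Ser_f302	ser	1,2	C8H22NO2Si2
Thr	Thr_M57	thr	1,2,3,4	C14H42NO3Si3
Thr	Thr_M85	thr	2,3,4	C14H42NO2Si3
Thr	Thr_f302	thr	1,2	C8H22NO2Si2
Asp	Asp_M57	oaa_m	1,2,3,4	C14H40NO4Si3
Asp	Asp_M85	oaa_m	2,3,4	C14H40NO3Si3
Asp	Asp_f302	oaa_m	1,2	C8H22NO2Si2
Glu	Glu_M57	akg	1,2,3,4,5	C14H42NO4Si3
Glu	Glu_M85	akg	2,3,4,5	C14H42NO3Si3
Glu	Glu_f302	akg	1,2	C8H22NO2Si2
Val	Val_f302	pyr	1,2	C8H22NO2Si2
Phe	Phe_f302	pep	1,2	C8H22NO2Si2
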