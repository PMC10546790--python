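# name lemna_core_A_ONS
# reactions 61
# ratio vRBC vRBO 1000.0
# ratio vKGDH_a vKGDH_b 1.0
# metabolite Glc_x x 6 external
# metabolite Gln_x x 5 external
# metabolite CO2_x x 1 external
# metabolite G6P_c c 6 balanced
# metabolite G6P_p p 6 balanced
# metabolite F6P_c c 6 balanced
# metabolite F6P_p p 6 balanced
# metabolite TP_c c 3 balanced
# metabolite TP_p p 3 balanced
# metabolite PGA_c c 3 balanced
# metabolite PGA_p p 3 balanced
# metabolite PEP_c c 3 balanced
# metabolite PEP_p p 3 balanced
# metabolite Pyr_c c 3 balanced
# metabolite Pyr_p p 3 balanced
# metabolite Pyr_m m 3 balanced
# metabolite P5P_c c 5 balanced
# metabolite P5P_p p 5 balanced
# metabolite S7P_c c 7 balanced
# metabolite S7P_p p 7 balanced
# metabolite E4P_c c 4 balanced
# metabolite E4P_p p 4 balanced
# metabolite RuBP_p p 5 balanced
# metabolite PG2_p p 2 balanced
# metabolite AcCoA_p p 2 balanced
# metabolite AcCoA_m m 2 balanced
# metabolite Cit_m m 6 balanced
# metabolite KG_m m 5 balanced
# metabolite OAA merged 4 balanced
# metabolite Glu_c c 5 balanced
# metabolite Gln_c c 5 balanced
# metabolite CO2_c merged 1 balanced
# metabolite AlaBM x 3 external
# metabolite GluBM x 5 external
# metabolite GlnBM x 5 external
# metabolite SerBM x 3 external
# metabolite GlyBM x 2 external
# metabolite C1BM x 1 external
# metabolite HisBM x 5 external
# metabolite PheBM x 9 external
# metabolite TyrBM x 9 external
# metabolite ValBM x 5 external
# metabolite LeuBM x 6 external
# metabolite IleBM x 6 external
# metabolite ThrBM x 4 external
# metabolite AsxBM x 4 external
# metabolite LysBM x 6 external
# metabolite GlycBM x 3 external
# metabolite FASBM x 2 external
# metabolite GlcBM x 6 external
# metabolite CitBM x 6 external
# metabolite MalBM x 4 external
# metabolite FrucBM x 6 external
# metabolite StBM x 6 external
# metabolite HPcBM x 6 external
vGlc_up	Glc_x#abcdef	G6P_c#abcdef	irr	0.0	3000.0
vGln_up	Gln_x#abcde	Gln_c#abcde	irr	0.0	3000.0
vPGI_c	G6P_c#abcdef	F6P_c#abcdef	rev	-3000.0	3000.0
vALD_c	F6P_c#abcdef	TP_c#cba + TP_c#def	rev	-3000.0	3000.0
vGAPDH_c	TP_c#abc	PGA_c#abc	rev	-3000.0	3000.0
vENO_c	PGA_c#abc	PEP_c#abc	rev	-3000.0	3000.0
vPK_c	PEP_c#abc	Pyr_c#abc	irr	0.0	3000.0
vPGI_p	G6P_p#abcdef	F6P_p#abcdef	rev	-3000.0	3000.0
vALD_p	F6P_p#abcdef	TP_p#cba + TP_p#def	rev	-3000.0	3000.0
vGAPDH_p	TP_p#abc	PGA_p#abc	rev	-3000.0	3000.0
vENO_p	PGA_p#abc	PEP_p#abc	rev	-3000.0	3000.0
vPK_p	PEP_p#abc	Pyr_p#abc	irr	0.0	3000.0
vG6PDH_c	G6P_c#abcdef	P5P_c#bcdef + CO2_c#a	irr	0.0	3000.0
vTK1_c	P5P_c#abcde + P5P_c#fghij	S7P_c#abfghij + TP_c#cde	rev	-3000.0	3000.0
vTK2_c	P5P_c#abcde + E4P_c#fghi	F6P_c#abfghi + TP_c#cde	rev	-3000.0	3000.0
vTA_c	S7P_c#abcdefg + TP_c#hij	E4P_c#defg + F6P_c#abchij	rev	-3000.0	3000.0
vG6PDH_p	G6P_p#abcdef	P5P_p#bcdef + CO2_c#a	irr	0.0	3000.0
vTK1_p	P5P_p#abcde + P5P_p#fghij	S7P_p#abfghij + TP_p#cde	rev	-3000.0	3000.0
vTK2_p	P5P_p#abcde + E4P_p#fghi	F6P_p#abfghi + TP_p#cde	rev	-3000.0	3000.0
vTA_p	S7P_p#abcdefg + TP_p#hij	E4P_p#defg + F6P_p#abchij	rev	-3000.0	3000.0
vT_G6P	G6P_c#abcdef	G6P_p#abcdef	rev	-3000.0	3000.0
vT_TP	TP_c#abc	TP_p#abc	rev	-3000.0	3000.0
vT_PEP	PEP_c#abc	PEP_p#abc	rev	-3000.0	3000.0
vT_PGA	PGA_c#abc	PGA_p#abc	rev	-3000.0	3000.0
vPRK	P5P_p#abcde	RuBP_p#abcde	irr	0.0	3000.0
vRBC	RuBP_p#abcde + CO2_c#f	PGA_p#fba + PGA_p#cde	irr	0.0	3000.0
vRBO	RuBP_p#abcde	PG2_p#ba + PGA_p#cde	irr	0.0	3000.0
vPR	PG2_p#ab + PG2_p#cd	PGA_p#abd + CO2_c#c	irr	0.0	3000.0
vPyr_cm	Pyr_c#abc	Pyr_m#abc	rev	-3000.0	3000.0
vPDH_p	Pyr_p#abc	AcCoA_p#bc + CO2_c#a	irr	0.0	3000.0
vPDH_m	Pyr_m#abc	AcCoA_m#bc + CO2_c#a	irr	0.0	3000.0
vCS	OAA#abcd + AcCoA_m#ef	Cit_m#dcbfea	irr	0.0	3000.0
vIDH	Cit_m#abcdef	KG_m#abcde + CO2_c#f	irr	0.0	3000.0
vKGDH_a	KG_m#abcde	OAA#bcde + CO2_c#a	irr	0.0	3000.0
vKGDH_b	KG_m#abcde	OAA#edcb + CO2_c#a	irr	0.0	3000.0
vPEPC	PEP_c#abc + CO2_c#d	OAA#abcd	rev	-3000.0	3000.0
vGlnGlu	Gln_c#abcde	Glu_c#abcde	rev	-3000.0	3000.0
vGluKG	Glu_c#abcde	KG_m#abcde	rev	-3000.0	3000.0
vCO2_out	CO2_c#a	CO2_x#a	irr	0.0	3000.0
vAlaP	Pyr_c#abc	AlaBM#abc	irr	0.0	3000.0
vGluP	Glu_c#abcde	GluBM#abcde	irr	0.0	3000.0
vGlnP	Gln_c#abcde	GlnBM#abcde	irr	0.0	3000.0
vSerP	PGA_p#abc	SerBM#abc	irr	0.0	3000.0
vGlyP	PGA_p#abc	GlyBM#ab + C1BM#c	irr	0.0	3000.0
vHisP	P5P_p#abcde	HisBM#abcde	irr	0.0	3000.0
vPheP	E4P_p#abcd + PEP_p#efg + PEP_p#hij	PheBM#hijfgabcd + CO2_c#e	irr	0.0	3000.0
vTyrP	E4P_p#abcd + PEP_p#efg + PEP_p#hij	TyrBM#hijfgabcd + CO2_c#e	irr	0.0	3000.0
vValP	Pyr_p#abc + Pyr_p#def	ValBM#defbc + CO2_c#a	irr	0.0	3000.0
vLeuP	Pyr_p#abc + Pyr_p#def + AcCoA_p#gh	LeuBM#ghefbc + CO2_c#a + CO2_c#d	irr	0.0	3000.0
vIleP	OAA#abcd + Pyr_p#efg	IleBM#abfgcd + CO2_c#e	irr	0.0	3000.0
vThrP	OAA#abcd	ThrBM#abcd	irr	0.0	3000.0
vAsxP	OAA#abcd	AsxBM#abcd	irr	0.0	3000.0
vLysP	OAA#abcd + Pyr_p#efg	LysBM#abcdfg + CO2_c#e	irr	0.0	3000.0
vGlyc_out	TP_c#abc	GlycBM#abc	irr	0.0	3000.0
vFASp	AcCoA_p#ab	FASBM#ab	irr	0.0	3000.0
vGlc_out	G6P_c#abcdef	GlcBM#abcdef	irr	0.0	3000.0
vCit_out	Cit_m#abcdef	CitBM#abcdef	irr	0.0	3000.0
vMal_out	OAA#abcd	MalBM#abcd	irr	0.0	3000.0
vFruc_out	F6P_c#abcdef	FrucBM#abcdef	irr	0.0	3000.0
vSt_out	G6P_p#abcdef	StBM#abcdef	irr	0.0	3000.0
vHPc_out	G6P_c#abcdef	HPcBM#abcdef	irr	0.0	3000.0
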