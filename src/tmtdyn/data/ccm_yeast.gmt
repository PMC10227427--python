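GLYCOLYSIS	Glycolysis / Embden-Meyerhof-Parnas pathway (S. cerevisiae)	HXK1	HXK2	GLK1	PGI1	PFK1	PFK2	FBA1	TPI1	TDH1	TDH2	TDH3	PGK1	GPM1	GPM2	GPM3	ENO1	ENO2	PYK2	CDC19
FERMENTATION	Pyruvate decarboxylation and alcoholic fermentation	PDC1	PDC5	PDC6	ADH1	ADH2	ADH3	ADH4	ADH5	ALD4	ALD6
TCA_CYCLE	Tricarboxylic acid cycle	CIT1	CIT2	CIT3	ACO1	ACO2	IDH1	IDH2	IDP1	KGD1	KGD2	LPD1	LSC1	LSC2	SDH1	SDH2	SDH3	SDH4	FUM1	MDH1	MDH2
GLUCONEOGENESIS_GLYOXYLATE	Gluconeogenesis and glyoxylate cycle	FBP1	PCK1	ICL1	MLS1	MDH2	CIT2	ACS1	ACH1
PENTOSE_PHOSPHATE	Pentose phosphate pathway	ZWF1	SOL3	SOL4	GND1	GND2	RKI1	RPE1	TKL1	TKL2	TAL1
STORAGE_CARBOHYDRATE	Trehalose and glycogen metabolism	TPS1	TPS2	TSL1	NTH1	NTH2	ATH1	GSY1	GSY2	GLG1	GLG2	GPH1	GDB1	PGM1	PGM2	UGP1
HEXOSE_TRANSPORT	Hexose transporter family	HXT1	HXT2	HXT3	HXT4	HXT5	HXT6	HXT7	GAL2
GLYCEROL_REDOX	Glycerol formation and redox balancing	GPD1	GPD2	GPP1	GPP2	GUT1	GUT2
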