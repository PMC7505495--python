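rods	GNGT1
rods	NRL
rods	PDE6G
rods	RHO
cones	ARR3
cones	CNGA3
cones	OPN1LW
cones	OPN1MW
cones	OPN1SW
cones	PDE6H
horizontal cells	LHX1
horizontal cells	LNP1
horizontal cells	ONECUT1
horizontal cells	VAT1L
bipolar cells	GRIK1
bipolar cells	IRX6
bipolar cells	LRTM1
bipolar cells	PCP2
bipolar cells	PRKCA
bipolar cells	TRPM1
bipolar cells	VSX1
bipolar cells	VSX2
amacrine cells	GAD1
amacrine cells	SLC6A9
amacrine cells	TFAP2A
amacrine cells	TFAP2B
ganglion cells	POU4F2
ganglion cells	NEFL
ganglion cells	NEFM
ganglion cells	RBPMS
ganglion cells	SLC17A6
ganglion cells	SNCG
ganglion cells	THY1
pigmented cells	BEST1
pigmented cells	MITF
pigmented cells	MLANA
pigmented cells	TJP1
pigmented cells	RPE65
glial cells	CRABP1
glial cells	GFAP
glial cells	GLUL
vascular cells	ACTA2
vascular cells	COL1A2
vascular cells	EGFL7
vascular cells	PDGFRB
vascular cells	PROCR
vascular cells	VWF
immune cells	AIF1
immune cells	CD2
immune cells	CD48
immune cells	CX3CR1
immune cells	HBB
immune cells	IL32
immune cells	JCHAIN
immune cells	LST1
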