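gene_symbol	protein_name	reference_only	CD1 P4	CD1 P9	MF1xCD1 P4	MF1xCD1 P9	hPSF	ihPSF	HUES1
ADAMTS4	ADAM-TS4	0		0.500			1.18	2.03	4.76
AGRN	Agrin	0							10.0
APOE	Apolipoprotein E	0							215
CLU	Clusterin	0							43.1
COL12A1	Collagen, type XII, alpha 1	1	2.60	1.91	8.23	6.44		0.470	
COL18A1	Collagen, type XVIII, alpha 1	0							5.83
COL1A1	Collagen, type I, alpha 1	0		1.14	1.45	3.70	1.02	7.36	54.3
COL1A2	Collagen, type I, alpha 2	0	0.439	0.520	1.34	3.26		3.06	18.1
COL2A1	Collagen, type II, alpha 1	0							1.2
COL3A1	Collagen, type III, alpha 1	1		0.490					
COL4A1	Collagen, type IV, alpha 1	0			0.253			1.63	5.52
COL4A2	Collagen, type IV, alpha 2	0			0.184			1.04	18.5
COL5A1	Collagen, type V, alpha 1	1			0.330				
COL5A2	Collagen, type V, alpha 2	1			0.640				
COL6A1	Collagen, type VI, alpha 1	1			0.800	1.46	0.740	5.23	
COL6A2	Collagen, type VI, alpha 2	1				0.960	0.980	4.49	
COL6A3	Collagen, type VI, alpha 3	1					1.25	8.41	
CYR61	CYR61	0	1.58	2.68	0.732		21.5	47.0	2.55
EGFL7	EGF-like protein 7	0							12.5
EMID2	Collagen, type XXVI, alpha 1	0							8.34
EMILIN1	EMILIN-1	0	13.7	27.3	13.0	34.7	24.9	49.7	13.2
EMILIN2	EMILIN-2	0				1.25			1.39
FBLN2	Fibulin-2	0	54.4	31.8	32.8	69.6			6.13
FBN1	Fibrillin-1	0	0.274		0.262	10.1		0.375	3.09
FBN2	Fibrillin-2	0				0.671			11.0
FGFBP3	FGF-binding protein 3	0							5.74
FN1	Fibronectin-1	0	99.1	117	95.1	118	2.34	57.2	81.9
HNRNPM	hnRNP M	0		1.00					15.9
HSP90B1	Endoplasmin	0					1.00	1.19	4.08
HSPG2	Perlecan	0	6.63	13.1	10.3	15.8		4.16	15.7
KRT1	Keratin, type II, cytoskeletal 1	0	8.78	12.9	6.65	11.6	107	70.5	13.9
LAMA1	Laminin alpha 1	0							1.97
LAMA5	Laminin alpha 5	0						0.219	1.82
LAMB1	Laminin beta 1	0						0.295	5.29
LAMC1	Laminin gamma 1	0						0.329	10.8
LEFTY2	TGF-beta 4	0							16.7
NID1	Nidogen-1	0			1.08			0.645	2.59
NID2	Nidogen-2	0	0.370	0.731		15.5			1.07
PKM2	Pyruvate kinase isozyme M1	0			0.796			1.76	4.62
THBS1	Thrombospondin-1	0	13.9	29.0	20.8	7.84	1.79	4.93	1.25
TNC	Tenascin C	0	1.17	3.21	2.91	4.58	12.3	17.2	4.23
VCAN	Versican	0					0.937	1.71	3.44
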