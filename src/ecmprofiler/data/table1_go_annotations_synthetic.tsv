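gene_symbol	go_id	evidence
ADAMTS4	GO:0005576	IEA
AGRN	GO:0005576	IEA
COL12A1	GO:0005576	IEA
COL18A1	GO:0005576	IEA
COL1A1	GO:0005576	IEA
COL1A2	GO:0005576	IEA
COL2A1	GO:0005576	IEA
COL3A1	GO:0005576	IEA
COL4A1	GO:0005576	IEA
COL4A2	GO:0005576	IEA
COL5A1	GO:0005576	IEA
COL5A2	GO:0005576	IEA
COL6A1	GO:0005576	IEA
COL6A2	GO:0005576	IEA
COL6A3	GO:0005576	IEA
CYR61	GO:0005576	IEA
EGFL7	GO:0005576	IEA
EMID2	GO:0005576	IEA
EMILIN1	GO:0005576	IEA
EMILIN2	GO:0005576	IEA
FBLN2	GO:0005576	IEA
FBN1	GO:0005576	IEA
FBN2	GO:0005576	IEA
FN1	GO:0005576	IEA
HNRNPM	GO:0005576	IEA
HSPG2	GO:0005576	IEA
KRT1	GO:0005576	IEA
LAMA1	GO:0005576	IEA
LAMA5	GO:0005576	IEA
LAMB1	GO:0005576	IEA
LAMC1	GO:0005576	IEA
NID1	GO:0005576	IEA
NID2	GO:0005576	IEA
THBS1	GO:0005576	IEA
TNC	GO:0005576	IEA
VCAN	GO:0005576	IEA
APOE	GO:0005615	IEA
CLU	GO:0005615	IEA
FGFBP3	GO:0005615	IEA
LEFTY2	GO:0005615	IEA
HSP90B1	GO:0009986	IEA
PKM2	GO:0005886	IEA
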