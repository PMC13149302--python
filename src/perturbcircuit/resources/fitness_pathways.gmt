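APOPTOSIS	cell-fitness pathway: apoptosis	BAX	BAK1	BCL2	BCL2L1	BCL2L11	MCL1	BID	BAD	PMAIP1	BBC3	CASP3	CASP7	CASP8	CASP9	APAF1	CYCS	XIAP	BIRC5	FAS	FASLG	TNFRSF10A	TNFRSF10B	TP53	CFLAR	DIABLO
CELL_CYCLE	cell-fitness pathway: cell cycle regulation	CCND1	CCND2	CCND3	CCNE1	CCNE2	CCNA2	CCNB1	CCNB2	CDK1	CDK2	CDK4	CDK6	CDKN1A	CDKN1B	CDKN2A	CDKN2B	RB1	E2F1	E2F2	MYC	MCM2	MCM3	MCM5	PCNA	CDC20	CDC25A	CDC25C	PLK1	AURKA	AURKB
CHECKPOINT	cell-fitness pathway: DNA-damage checkpoint control	ATM	ATR	CHEK1	CHEK2	TP53	MDM2	WEE1	CDC25A	H2AX	MDC1	TP53BP1	BRCA1	BRCA2	RAD51	RAD17	RAD9A	HUS1	RRM2B	GADD45A	SFN	CLSPN	TOPBP1	TIMELESS	TIPIN
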