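R_MRNA_SPLICING	mRNA splicing	SNRNP200	PTBP1	YBX1	SMC1A	HNRNPA0	HNRNPF	HNRNPH1	PRPF8	EFTUD2	DHX9	PCBP2	SRSF9	HNRNPA1	HNRNPL	HNRNPU	RBMX	HNRNPR
R_MRNA_PROCESSING	mRNA processing	SNRNP200	PTBP1	YBX1	SMC1A	HNRNPA0	HNRNPF	HNRNPH1	PRPF8	EFTUD2	DHX9	PCBP2	SRSF9	HNRNPA1	HNRNPL	HNRNPU	RBMX	HNRNPR
R_GENE_EXPRESSION	Gene expression	SNRNP200	PTBP1	IGF2BP3	YBX1	RPS3A	ELAVL1	RPLP0	HNRNPA0	RPL18	HNRNPF	EEF1G	EEF1A1	IGF2BP1	RPL14	RPS4X	RPS2	PCBP2	RPS8	HNRNPA1	RPL10A	PABPC1	HNRNPR	EIF4A1	SF1	SMC1A	HNRNPH1	RPL11	PRPF8	RPL7A	EFTUD2	PARP1	KHSRP	PPP2R1A	DHX9	SRSF9	RPL8	HNRNPU	HNRNPL	RBMX	TRIM28
R_METABOLISM_OF_PROTEINS	Metabolism of proteins	EIF4A1	HSPD1	RPS3A	LMNA	CCT6A	CCT3	RPLP0	RPL18	PDIA3	RPL11	EEF1G	EEF1A1	HSP90B1	CCT2	RPL7A	HSPA5	PDIA6	CCT8	TCP1	RPL14	RPS4X	RPS2	RPL8	RPS8	HSPA9	ATP5B	RPL10A	NOP56	PABPC1
R_3UTR_TRANSLATIONAL_REGULATION	3'-UTR-mediated translational regulation	EIF4A1	RPL7A	RPS3A	RPL14	RPS4X	RPS2	RPL8	RPS8	RPLP0	RPL18	RPL10A	PABPC1	RPL11
R_NHEJ	Nonhomologous end joining (NHEJ)	XRCC5	PRKDC	XRCC6
R_APOPTOSIS	Apoptosis	LMNB1	CAD	LMNA	TJP1	YWHAE	DSG2	YWHAQ	DSP	KPNB1	PLEC
R_PROTEIN_FOLDING	Protein folding	CCT2	CCT8	NOP56	TCP1	CCT6A	CCT3
R_CELL_CELL_COMMUNICATION	Cell-cell communication	FLNA	ACTN4	MLLT4	JUP	KRT14	IQGAP1	KRT5	PLEC
R_CELL_CYCLE	Cell cycle	LMNB1	DYNC1H1	LMNA	CDK1	SMC1A	TOP2A	TP53	EMD	TPR	PPP2R1A	NUP93	MCM7	YWHAE	NUMA1	NUP205	NPM1
R_CELL_CYCLE_MITOTIC	Cell cycle, mitotic	LMNB1	EMD	TPR	DYNC1H1	PPP2R1A	LMNA	CDK1	YWHAE	SMC1A	MCM7	NUP93	NUMA1	TOP2A	NUP205
R_DSB_REPAIR	Double-strand break repair	XRCC5	PRKDC	XRCC6
R_MITOTIC_MMG1	Mitotic M-M/G1 phases	LMNB1	EMD	TPR	PPP2R1A	LMNA	CDK1	SMC1A	MCM7	NUP93	NUP205
R_DISEASE	Disease	RPS3A	CDK1	RPLP0	RPL18	RPL11	KPNB1	RPL7A	TPR	PPP2R1A	RPL14	RPS2	RPS4X	NUP93	RPL8	XRCC5	RPS8	HDAC2	RPL10A	NUP205	XRCC6	NPM1
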