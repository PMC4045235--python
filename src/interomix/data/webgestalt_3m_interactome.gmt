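W_GENE_EXPRESSION	Gene expression	RPS8	HNRNPA1	PRPF8	RPS2	DHX9	HNRNPA0	HNRNPH1	EEF1G	EEF1A1	NUP205	RPL11	RPL18	EFTUD2	YBX1	HNRNPL	HNRNPU	PABPC1	PCBP2	SNRNP200	PTBP1	HNRNPF	RPL8	EIF4A1	RPL10A	TRIM28	RPLP0	RPS3A	RPS4X	RPL7A	TPR	HNRNPR	RBMX	NUP93	RPL14	SMC1A	SRSF9
W_MRNA_PROCESSING	mRNA processing	HNRNPA1	PRPF8	SNRNP200	PTBP1	DHX9	HNRNPF	HNRNPA0	HNRNPH1	NUP205	TPR	HNRNPR	RBMX	EFTUD2	NUP93	SMC1A	HNRNPL	YBX1	HNRNPU	SRSF9	PCBP2
W_VEGF_SIGNALLING	VEGF and VEGFR signalling network	HNRNPA1	HSP90B1	JUP	COPA	IQGAP1	TP53	NPM1	TJP1	YWHAE	RPL11	CAD	PA2G4	PPP2R1A	IGF2BP1	HSPD1	ENO1	KPNB1	KRT5	GAPDH	PRKDC	HSP90AB1	KRT14	LDHA	YWHAQ	EIF4A1	NCL	DSP	CDK1	TRIM28	XRCC5	MLLT4	CLTC	XRCC6	ACTN4	DDX5	KPNA2	RUVBL2	HDAC2
W_INSULIN_PATHWAY	Insulin pathway	HNRNPA1	HSP90B1	JUP	COPA	IQGAP1	TP53	NPM1	TJP1	YWHAE	RPL11	CAD	PA2G4	PPP2R1A	IGF2BP1	HSPD1	ENO1	KPNB1	KRT5	GAPDH	PRKDC	KRT14	LDHA	YWHAQ	EIF4A1	NCL	DSP	CDK1	TRIM28	XRCC5	MLLT4	CLTC	XRCC6	ACTN4	DDX5	KPNA2	RUVBL2	HDAC2
W_MTOR_SIGNALLING	mTOR signalling pathway	HNRNPA1	HSP90B1	JUP	COPA	IQGAP1	TP53	NPM1	TJP1	YWHAE	RPL11	CAD	PA2G4	PPP2R1A	IGF2BP1	HSPD1	ENO1	KPNB1	KRT5	GAPDH	PRKDC	KRT14	LDHA	YWHAQ	EIF4A1	NCL	DSP	CDK1	TRIM28	XRCC5	MLLT4	CLTC	XRCC6	ACTN4	DDX5	KPNA2	RUVBL2	HDAC2
W_IGF1_PATHWAY	IGF1 pathway	HNRNPA1	HSP90B1	JUP	COPA	IQGAP1	TP53	NPM1	TJP1	YWHAE	RPL11	CAD	PA2G4	PPP2R1A	IGF2BP1	HSPD1	ENO1	KPNB1	KRT5	GAPDH	PRKDC	KRT14	LDHA	YWHAQ	EIF4A1	NCL	DSP	CDK1	TRIM28	XRCC5	MLLT4	CLTC	XRCC6	ACTN4	DDX5	KPNA2	RUVBL2	HDAC2
W_MRNA_SPLICING	mRNA splicing	HNRNPA1	PRPF8	SNRNP200	PTPB1	DHX9	HNRNPF	HNRNPA0	HNRNPH1	HNRNPR	RBMX	EFTUD2	SMC1A	HNRNPL	YBX1	HNRNPU	SRSF9	PCBP2
W_METABOLISM_OF_PROTEINS	Metabolism of proteins	RPS8	CCT2	RPS2	RPL8	CCT3	PDIA3	EIF4A1	RPL10A	EEF1G	RPLP0	CCT8	EEF1A1	RPS3A	RPL11	RPL7A	RPS4X	RPL18	TCP1	RPL14	CCT6A	PABPC1
W_3UTR_TRANSLATIONAL_REGULATION	3'-UTR-mediated translational regulation	RPL7A	RPS8	RPS4X	RPS2	RPL18	RPL8	RPL14	EIF4A1	RPL10A	RPLP0	PABPC1	RPS3A	RPL11
W_WNT_SIGNALLING	Wnt signalling network	HNRNPA1	PA2G4	PRKDC	XRCC6	YWHAQ	RUVBL2	FLNA	IGF2BP1	YWHAE	HDAC2	XRCC5
W_CHAPERONIN_FOLDING	Chaperonin-mediated protein folding	CCT3	CCT6A	CCT2	TCP1	CCT8
W_APOPTOSIS	Apoptosis	TJP1	PLEC	LMNB1	DSP	KPNB1	DSG2	LMNA	TP53
W_NHEJ	Nonhomologous end joining (NHEJ)	PRKDC	XRCC6	XRCC5
W_CELL_CELL_COMMUNICATION	Cell-cell communication	ACTN4	MLLT4	PLEC	FLNA	JUP	IQGAP1
W_CELL_CYCLE_MITOTIC	Cell cycle, mitotic	DYNC1H1	TOP2A	NUMA1	PPP2R1A	SMC1A	YWHAE	MCM7	CDK1
W_MITOTIC_G2_G2M	Mitotic G2-G2/M phases	DYNC1H1	NUMA1	YWHAE	PPP2R1A	CDK1
W_DSB_REPAIR	Double-strand break repair	PRKDC	XRCC6	XRCC5
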