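human_mirna	human_location	human_host	mouse_mirna	mouse_location	mouse_host	chicken_mirna	chicken_location	chicken_host
let-7g	intron 2, 3	WDR82	let-7g	intron 2	Wdr82	let-7g	intron 2	WDR82_CHICK
mir-101-2	intron 4, 7, 8	RCL1	mir-101b	intron 8	Rcl1	mir-101	intron 8	RCL1
mir-103a-1	intron 2, 5	PANK3	mir-103-1	intron 5	Pank3	mir-103-1	intron 4, 5	PANK3
mir-107	intron 4, 5	PANK1	mir-107	intron 5	Pank1	mir-107	intron 5	PANK1
mir-126	intron 5, 6, 7	EGFL7	mir-126	exon 4; intron 1, 6, 7	Egfl7	mir-126	intron 7	EGFL7
mir-128-1	intron 7, 15, 18	R3HDM1	mir-128-1	intron 19	R3hdm1	mir-128-1	intron 18	R3HDM1
mir-128-2	intron 3, 6, 17, 18	ARPP21	mir-128-2	intron 14, 15, 16, 17, 19	Arpp21	mir-128-2	intron 16	ARPP21
mir-1306	5′-UTR	DGCR8	mir-1306	exon 1, 2, 3	Dgcr8	mir-1306	5′-UTR	DGCR8
mir-140	intron 3, 6, 7, 9, 14, 16	WWP2	mir-140	intron 16	Wwp2	mir-140	intron 16, 17	WWP2
mir-15b	intron 1, 2, 3, 4, 5	SMC4	mir-15b	intron 5	Smc4	mir-15b	intron 4	SMC4
mir-16-2	intron 1, 2, 3, 4, 5	SMC4	mir-16-2	intron 5	Smc4	mir-16-2	intron 4	SMC4
mir-190a	intron 22, 27, 51, 53	TLN2	mir-190a	intron 53	Tln2	mir-190	intron 54	TLN2
mir-211	intron 4, 5, 6, 7	TRPM1	mir-211	intron 1, 2, 4, 5, 6	Trpm1	mir-204-2 (orthologue)	intron 5	TRPM1
mir-218-1	intron 14, 15, 16	SLIT2	mir-218-1	intron 1, 8, 14, 15, 16	Slit2	mir-218-1	intron 13, 15	Q90XG3_CHICK (orthologue)
mir-218-2	intron 4, 14	SLIT3	mir-218-2	intron 14	Slit3	mir-218-2	intron 1, 9	Q90Z43_CHICK (orthologue)
mir-23b	intron 4, 5, 6, 14, 15	C9orf3	mir-23b	intron 3, 15	2010111I01Rik (orthologue)	mir-23b	intron 15	C9orf3
mir-24-1	exon 7; intron 4, 5, 6, 14, 15	C9orf3	mir-24-1	intron 3, 15	2010111I01Rik (orthologue)	mir-24	3′-UTR	C9orf3
mir-26a-1	intron 2, 4, 5	CTDSPL	mir-26a-1	intron 4, 5	Ctdspl	mir-26a	intron 5	CTDSL_CHICK
mir-27b	intron 4, 5, 6, 14, 15	C9orf3	mir-27b	intron 3, 15	2010111I01Rik (orthologue)	mir-27b	intron 15	C9orf3
mir-301a	intron 1	SKA2	mir-301a	intron 1	SKA2 (Fam33a)	mir-301b (orthologue)	intron 1	SKA2
mir-30c-1	intron 1, 2, 3, 4, 5, 6, 10	NFYC	mir-30c-1	intron 3, 4, 5	Nfyc	mir-30c-1	intron 4	NFYC
mir-30e	intron 1, 2, 3, 4, 5, 6, 10	NFYC	mir-30e	intron 3, 4, 5	Nfyc	mir-30e	intron 4	NFYC
mir-32	intron 8, 12, 14	TMEM245 (C9orf5)	mir-32	intron 8, 12, 14	TMEM245	mir-32	intron 23	Tmem245 (C9orf5)
mir-33a	intron 1, 2, 9, 10, 16, 18, 19	SREBF2	mir-33	intron 16	Srebf2	mir-33 (mir-33-1)	intron 13	SREBF2
mir-455	intron 5, 6, 7, 10	COL27A1	mir-455	intron 7, 10	Col27a1	mir-455	intron 18	COL27A1
mir-499a	intron 20	MYH7B	mir-499	intron 19	Myh7b	mir-499	intron 18, 19	MYH7B
mir-7-1	intron 1, 3, 15, 16	HNRNPK	mir-7a-1	intron 2, 3, 5, 7, 11, 14, 15, 17	Hnrnpk	mir-7-1	intron 15	HNRNPK
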