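mirna	location	host	host_class
hsa-let-7a-3	exon 5	RP4-695O20__B.10	protein_coding
hsa-mir-107	intron 4, 5, 6	PANK1	protein_coding
hsa-mir-10a	5′-UTR; intron 1	HOXB3	protein_coding
hsa-mir-10a	5′-UTR	HOXB4	protein_coding
hsa-mir-10b	intron 1	HOXD3	protein_coding
hsa-mir-1-1	intron 1, 2	C20orf166	protein_coding
hsa-mir-126	intron 5, 6, 7	EGFL7	protein_coding
hsa-mir-139	intron 1, 2, 3	PDE2A	protein_coding
hsa-mir-140	intron 3, 6, 7, 9, 13, 14, 16	WWP2	protein_coding
hsa-mir-148b	intron 1, 2	COPZ1	protein_coding
hsa-mir-152	intron 1, 2	COPZ2	protein_coding
hsa-mir-188	intron 3	CLCN5	protein_coding
hsa-mir-191	intron 1	DALRD3	protein_coding
hsa-mir-196a-1	intron 1	HOXB7	protein_coding
hsa-mir-196b	exon 1, 2, 3	HOXA9	protein_coding
hsa-mir-196b	intron 1	RP1-170O19.20	protein_coding
hsa-mir-198	3′-UTR	FSTL1	protein_coding
hsa-mir-204	intron 3, 4, 5, 6, 7	TRPM3	protein_coding
hsa-mir-23b	intron 4, 5, 6, 14, 15	C9orf3	protein_coding
hsa-mir-24-1	exon 7; intron 4, 5, 14, 15	C9orf3	protein_coding
hsa-mir-25	intron 2, 4, 8, 12, 13	MCM7	protein_coding
hsa-mir-27b	intron 4, 5, 6, 14, 15	C9orf3	protein_coding
hsa-mir-342	intron 2, 3, 4	EVL	protein_coding
hsa-mir-425	intron 1	DALRD3	protein_coding
hsa-mir-448	intron 4, 5	HTR2C	protein_coding
hsa-mir-483	intron 2, 3, 5	IGF2	protein_coding
hsa-mir-483	intron 5	INS-IGF2	protein_coding
hsa-mir-548c-1	intron 14, 15, 16	ATAD2	protein_coding
hsa-mir-570	intron 3	MUC20	protein_coding
hsa-mir-582	intron 1, 2, 3	PDE4D	protein_coding
hsa-mir-615	intron 1	HOXC5	protein_coding
hsa-mir-615	intron 1	HOXC4	protein_coding
hsa-mir-744	intron 1, 2, 3, 4, 5	MAP2K4	protein_coding
hsa-mir-9-1	intron 1, 2	C1orf61	protein_coding
hsa-mir-124-1	exon 1, 3, 4	LINC00599	ncRNA
hsa-mir-124-2	intron 1	RP11-32K4.2	ncRNA
hsa-mir-137	exon 3	MIR137HG	ncRNA
hsa-mir-17	exon 3; intron 3	MIR17HG	ncRNA
hsa-mir-193b	intron 1	RP11-65J21.3	ncRNA
hsa-mir-205	exon 2, 4; intron 2, 3	MIR205HG	ncRNA
hsa-mir-20a	exon 3; intron 3	MIR17HG	ncRNA
hsa-mir-30a	intron 3	LINC00472	ncRNA
hsa-mir-31	intron 1	MIR31HG	ncRNA
hsa-mir-370	intron 5	MEG8	ncRNA
hsa-mir-9-2	exon 3, 4; intron 2, 3	LINC00461	ncRNA
hsa-mir-9-3	intron 1	CTD-2335A18.1	ncRNA
hsa-mir-99a	intron 1, 3, 5, 6	LINC00478	ncRNA
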