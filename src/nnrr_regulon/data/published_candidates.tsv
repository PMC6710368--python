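query	fc_mutant	fc_wt	locus_tag	gene_name	product	position	motif	operon_structure
bll0225	–2.7	3.1	Bdiaspc4_00775	phbB	Acetoacetyl-CoA reductase	–86	TTGATGTCCGTCAA	–
blr0314	–4.8	23.1	Bdiaspc4_01230	nosR	Regulatory protein NosR	–131	TTGATCCAGCGCAA	blr0314-blr0320
blr0315	–6.4	25.7	Bdiaspc4_01235	nosZ	TAT-dependent nitrous-oxide reductase	–	–	–
blr0316	–6.4	15.4	Bdiaspc4_01240	nosD	Nitrous oxide reductase family maturation protein NosD	–	–	–
blr0317	–7.5	13.7	Bdiaspc4_01245	nosF	ABC transporter ATP-binding protein	–	–	–
blr0318	–9.3	23.1	Bdiaspc4_01250	nosY	ABC transporter permease	–	–	–
blr0319	–6.2	10.2	Bdiaspc4_01255	nosL	Copper resistance protein CopZ	–	-	–
blr0320	–6.0	13.1	Bdiaspc4_01260	nosX	FAD:protein FMN transferase	–	–	–
blr0964	–4.3	2.0	Bdiaspc4_04660	–	NAD(P)/FAD-dependent oxidoreductase	–41	TTGATCTATGTCAT	–
blr0984	–5.6	2.4	Bdiaspc4_04770	–	AraC family transcriptional regulator	–245	TTGCTGCGGAGCAG	–
blr1311	–7.6	52.2	Bdiaspc4_06505	–	OmpW family protein	–60	TTGATCGGCGTCAA	–
bll1766	–7.1	19.6	Bdiaspc4_08945	–	OmpW family protein	–228	TTGATTGGTATCAA	–
blr1883	–2.6	9.5	Bdiaspc4_09550	rpoN1	RNA polymerase sigma-54 factor	–81	TTGCGCGACATCAA	–
bll1944	–3.7	8.5	Bdiaspc4_09875	–	Porin family protein	–174	TGGAGCGACACCAA	–
blr2006	–2.3	2.1	Bdiaspc4_10180	id676	Hypothetical protein	–451	TTGATCAGGTGCAA	–
bll2007	–8.3	56.9	Bdiaspc4_10185	hemN1	Oxygen-independent coproporphyrinogen III oxidase	–138	TTGACATAACGCAA	–
bll2330	–4.2	21.6	Bdiaspc4_11930	–	VOC family protein	–73	TTGATCCAGATCAA	bll2330-bll2329-bsl2328
bll2329	–3.7	7.2	Bdiaspc4_11925	–	FAD-dependent oxidoreductase	–	–	–
bsl2328	–3.5	6.6	Bdiaspc4_11920	–	DUF2783 domain-containing protein	–	–	–
bll2388	–11.3	15.2	Bdiaspc4_12230	cy2	Cytochrome c family protein	–435	TTGCGCCGGATCAG	–
bll2664	–2.3	3.9	Bdiaspc4_13755	–	DUF1254 domain-containing protein	–384	CTGCTCGACCTCAA	bll2664-bll2663
blr2763	–2.1	58.7	Bdiaspc4_14290	ccoN/fixN	Cytochrome-c oxidase, cbb3-type subunit I	–70	TTGATTTCAATCAA	blr2763-blr2764-bsr2765-blr2766
blr2764	–2.9	55.5	Bdiaspc4_14295	ccoO/fixO	Cytochrome-c oxidase, cbb3-type subunit II	–	–	–
blr2932	–7.6	7.3	Bdiaspc4_15155	–	Methyl-accepting chemotaxis protein	–124	TCGAGCCGGCTCAA	–
blr2933	–6.2	2.8	Bdiaspc4_15160	–	PAS domain S-box protein	–294	TCGGGCCGGCTCAA	–
bsr3073	–3.8	4.2	Bdiaspc4_15875	–	Hypothetical protein	–101	TTGACGCGGATCAA	–
bsl3211	–35.6	36.5	Bdiaspc4_16610	–	Hypothetical protein	–411	TTGATCGCGATGAA	–
blr3212	–105.4	53.8	Bdiaspc4_16615	norE	Cytochrome c oxidase subunit 3 family protein	–106	TTGCGTCGGCGCAA	blr3212-bsr3213
bsr3213	–14.6	7.5	Bdiaspc4_16620	–	Hypothetical protein	–	–	–
blr3214	–70.4	81.2	Bdiaspc4_16625	norC	Cytochrome c	–87	TTGCGCCCTGACAA	blr3214-blr3217
blr3215	–159.2	71.2	Bdiaspc4_16630	norB	Nitric oxide reductase subunit B	–	–	–
blr3216	–69.9	56.3	Bdiaspc4_16635	norQ	CbbQ/NirQ/NorQ/GpvN family protein	–	–	–
blr3217	–16.8	17.6	Bdiaspc4_16640	norD	VWA domain-containing protein	–	–	–
bll3611	–4.3	2.3	Bdiaspc4_18640	–	Caspase family protein	–330	TTGAACCACGTCAG	–
bll3835	–6.0	31.6	Bdiaspc4_19825	–	PepSY domain-containing protein	–93	TTGCTGCAAATCAA	–
blr4191	–6.7	6.0	Bdiaspc4_21720	–	Histidine kinase	–187	TTGATCTGGATCAA	–
blr4352	–7.5	3.2	Bdiaspc4_22595	–	Porin family protein	–433	TTGCGGGCGTGCAA	–
bsl4623	–3.4	4.9	Bdiaspc4_24190	–	Hypothetical protein	–71	TTGATGAAGATCAA	–
blr4770	–2.8	2.3	Bdiaspc4_25015	–	Lytic transglycosylase domain-containing protein	–246	TTGCGTCGGATCGA	–
bll5026	–7.0	2.3	Bdiaspc4_26405	hppa	K+-insensitive pyrophosphate-energized proton pump	–83	TTGTTCGAAATCAA	–
blr5774	–2.7	11.7	Bdiaspc4_30495	–	NAD(P)/FAD-dependent oxidoreductase	–459	TTGATCTTGCTCAA	blr5774-blr5775-bsr5776
blr5775	–4.1	10.8	Bdiaspc4_30500	trxC	Thioredoxin TrxC	–	–	–
bsr5776	–2.7	26.2	Bdiaspc4_30505	–	DUF2892 domain-containing protein	–	–	–
bll5842	–3.3	2.3	Bdiaspc4_30840	flaF	Flagellar biosynthesis regulatory protein FlaF	–43	TTAAGCGCGTTCAA	–
bll6222	–17.1	17.8	Bdiaspc4_32820	–	Group III truncated hemoglobin	–89	TTGCGCTGCGACAA	–
blr6437	–5.7	2.1	Bdiaspc4_33940	–	SMP-30/gluconolactonase/LRE family protein	–80	TTGACAGGTCTCAA	–
bll6496	–4.0	2.1	Bdiaspc4_34245	–	EAL domain-containing protein	–374	ATGCCCTGGATCAA	–
blr7084	–4.1	4.4	Bdiaspc4_37380	nnrR	CRP/FNR family transcriptional regulator	–66	TTGCGCTATCGCAA	–
bsl7085	–29.2	133.8	Bdiaspc4_37385	–	DUF1858 domain-containing protein	–62	TTGCGCTCCAACAA	–
bll7086	–4.3	43.8	Bdiaspc4_37390	hemN2	Oxygen-independent coproporphyrinogen III oxidase	–140	TTGCGCGAGCGCAA	–
blr7089	–21	161.4	Bdiaspc4_37405	nirK	Nitrite reductase, copper-containing	–74	TTGTTGCAGCGCAA	–
blr7544	–5.3	2.2	Bdiaspc4_39800	cycA	Cytochrome c family protein	–137	TTGTTGCAGCGCAA	–
bll7628	–10.3	10.1	Bdiaspc4_40255	–	Sterol-binding protein	–48	TTGTTCCCGCTCAA	bll7628-bll7627
bll7627	–15	75.3	Bdiaspc4_40250	–	U32 family peptidase	–	–	–
blr7684	–4.0	2.7	Bdiaspc4_40605	–	Hypothetical protein	–399	TTGATGTAGGTCGA	blr7684-blr7685
blr7685	–3.4	2.4	Bdiaspc4_40610	–	PilZ domain-containing protein	–	–	–
bll7787	–3.1	23.0	Bdiaspc4_41200	–	Hypothetical protein	–118	TTGACCCAGATCAA	–
blr7961	–3.3	43.7	Bdiaspc4_42105	–	Hsp20/alpha crystallin family protein	–82	TTGAGACAAATCAA	–
bll7982	–4.3	31.2	Bdiaspc4_42210	–	Class I SAM-dependent methyltransferase	–96	TTGATCTGAAACAA	bll7982-bll7981
bll7981	–5.9	22.1	Bdiaspc4_42205	–	Dehydrogenase	–	–	–
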