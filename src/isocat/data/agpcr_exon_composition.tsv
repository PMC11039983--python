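gene	old_symbol	n_transcripts	n_start_exon_classes	n_end_exon_classes	mean_exons_per_transcript	n_all_exons	median_exons_per_transcript
ADGRA1	GPR123	6	6	2	6	14	4.5
ADGRA2	GPR124	5	2	1	18	21	18.4
ADGRA3	GPR125	11	5	8	32	45	18
ADGRB1	BAI1	39	25	9	46	80	26
ADGRB2	BAI2	53	7	7	37	51	30
ADGRB3	BAI3	7	4	3	35	42	31
ADGRC1	CELSR1	18	12	11	43	66	34
ADGRC2	CELSR2	7	4	3	33	40	34
ADGRC3	CELSR3	11	6	5	84	95	35
ADGRD1	GPR133	22	10	7	31	48	22.5
ADGRD2	GPR144	5	5	4	22	31	4
ADGRE1	EMR1	10	4	4	24	32	18
ADGRE2	EMR2	72	11	20	44	75	18
ADGRE3	EMR3	10	5	6	15	26	14
ADGRE4P	EMR4	10	8	9	19	36	16
ADGRE5	CD97	5	2	1	21	24	19
ADGRF1	GPR110	8	3	2	13	18	13
ADGRF2	GPR111	3	1	3	11	15	10
ADGRF3	GPR113	24	5	8	23	36	13
ADGRF4	GPR115	7	4	1	8	13	10
ADGRF5	GPR116	26	6	5	27	38	22
ADGRG1	GPR56	82	16	7	33	56	15
ADGRG2	GPR64	30	9	6	33	48	28
ADGRG3	GPR97	9	2	1	11	14	11
ADGRG4	GPR112	12	12	6	26	44	7
ADGRG5	GPR114	15	7	9	29	45	11
ADGRG6	Gpr126	19	8	4	32	44	25
ADGRG7	Gpr128	7	2	3	23	28	15
ADGRL1	LPHN1	33	10	9	49	68	24
ADGRL2	LPHN2	79	25	18	39	82	21
ADGRL3	LPHN3	113	37	15	47	99	24
ADGRL4	ELTD1	2	1	2	15	18	12
ADGRV1	VLGR1	37	16	9	104	129	88
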