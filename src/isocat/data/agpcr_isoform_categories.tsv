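gene	old_symbol	ntf_variability	cterm_variability	tmd_variability	any_soluble_nt	any_anchored_nt	any_ctf	n_signal_peptides	chimeric_partners
ADGRA1	GPR123	0	0	1	0	1	1	0	
ADGRA2	GPR124	1	0	1	0	0	0	1	
ADGRA3	GPR125	1	0	0	0	1	1	2	LOC100505912
ADGRB1	BAI1	1	1	1	1	1	1	1	
ADGRB2	BAI2	1	1	1	0	1	1	2	
ADGRB3	BAI3	1	0	0	1	0	1	1	
ADGRC1	CELSR1	1	1	0	1	0	1	1	
ADGRC2	CELSR2	1	1	0	0	0	0	1	
ADGRC3	CELSR3	1	1	1	1	1	0	2	NCKIPSD,SLC26A6
ADGRD1	GPR133	1	1	1	1	1	1	2	
ADGRD2	GPR144	1	1	0	1	0	0	0	
ADGRE1	EMR1	1	0	1	1	0	0	1	
ADGRE2	EMR2	1	1	1	1	1	1	1	
ADGRE3	EMR3	1	0	0	1	0	1	1	
ADGRE4P	EMR4	0	0	0	1	0	0	0	
ADGRE5	CD97	1	1	1	0	0	0	1	
ADGRF1	GPR110	1	0	0	1	0	1	1	
ADGRF2	GPR111	1	1	0	0	0	1	1	ADGRF4
ADGRF3	GPR113	1	1	0	0	1	1	2	
ADGRF4	GPR115	1	0	0	0	0	1	1	
ADGRF5	GPR116	1	1	0	0	0	1	1	
ADGRG1	GPR56	1	1	1	0	0	1	2	ADGRG3
ADGRG2	GPR64	1	1	1	1	0	1	1	
ADGRG3	GPR97	0	0	1	0	1	1	1	
ADGRG4	GPR112	1	0	0	1	1	0	1	
ADGRG5	GPR114	1	0	0	1	1	0	1	LOC107984889,ADGRG1
ADGRG6	Gpr126	1	1	1	1	1	0	2	
ADGRG7	Gpr128	0	1	0	0	0	1	1	TFG
ADGRL1	LPHN1	1	1	0	1	1	1	1	ASF1B
ADGRL2	LPHN2	1	1	1	0	0	0	1	
ADGRL3	LPHN3	1	1	1	0	1	1	1	
ADGRL4	ELTD1	1	0	0	0	0	0	1	LOC107984998
ADGRV1	VLGR1	1	1	0	1	1	0	1	
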