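amino_acid	codon	taenia_saginata	homo_sapiens	bos_taurus
Phe	UUU	1.87	0.97	0.87
Phe	UUC	0.13	1.03	1.13
Leu	UUA	2.90	0.50	1.71
Leu	UUG	2.28	1.00	1.35
Leu	CUU	0.61	0.81	0.73
Leu	CUC	0.04	1.07	0.93
Leu	CUA	0.03	0.46	0.58
Leu	CUG	0.13	2.33	1.69
Ile	AUU	1.51	1.13	0.92
Ile	AUC	0.11	1.37	1.01
Ile	AUA	1.38	0.50	1.07
Val	GUU	2.02	0.79	0.69
Val	GUC	0.09	0.90	0.82
Val	GUA	0.59	0.52	0.72
Val	GUG	1.30	1.79	1.76
Ser	UCU	1.96	1.15	0.95
Ser	UCC	0.04	1.17	1.06
Ser	UCA	1.02	0.93	1.40
Ser	UCG	0.60	0.36	0.43
Ser	AGU	2.28	0.98	0.80
Ser	AGC	0.10	1.42	1.53
Pro	CCU	2.16	1.20	0.94
Pro	CCC	0.21	1.22	1.01
Pro	CCA	0.98	1.14	1.45
Pro	CCG	0.20	0.45	0.59
Thr	ACU	3.16	1.03	0.87
Thr	ACC	0.07	1.32	1.09
Thr	ACA	0.40	1.19	1.44
Thr	ACG	0.36	0.46	0.60
Ala	GCU	2.70	1.01	0.97
Ala	GCC	0.22	1.12	1.13
Ala	GCA	0.43	1.18	1.30
Ala	GCG	0.65	0.07	0.60
Tyr	UAU	1.91	0.71	0.90
Tyr	UAC	0.09	1.29	1.10
His	CAU	1.92	0.85	0.88
His	CAC	0.06	1.15	1.12
Gln	CAA	1.22	0.49	0.71
Gln	CAG	0.68	1.51	1.29
Asn	AAU	1.95	0.98	0.87
Asn	AAC	0.05	1.02	1.13
Lys	AAA	1.10	0.88	0.89
Lys	AAG	0.90	1.12	1.11
Asp	GAU	1.87	0.99	0.85
Asp	GAC	0.13	1.01	1.15
Glu	GAA	0.81	0.85	0.92
Glu	GAG	1.19	1.15	1.08
Cys	UGU	1.82	0.95	0.78
Cys	UGC	0.18	1.05	1.22
Arg	CGU	3.11	0.54	0.26
Arg	CGC	0.05	1.11	0.52
Arg	CGA	0.08	0.76	0.27
Arg	CGG	0.33	1.31	0.73
Arg	AGA	2.23	1.18	2.16
Arg	AGG	0.19	1.01	2.07
Gly	GGU	2.72	0.71	1.51
Gly	GGC	0.14	1.35	1.01
Gly	GGA	0.59	1.01	1.25
Gly	GGG	0.55	0.93	1.23
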