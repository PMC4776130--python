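residue	exp_pka	pHtMD	pHtMD_dev	CpHMD	CpHMD_dev	PROPKA	PROPKA_dev	include	notes
Asp19	2.21	-	-	4.1	1.89	4.22	2.01	false	pHtMD: no prediction possible
Asp21	6.54	-	-	-	-	2.29	4.25	false	pHtMD and CpHMD: no prediction possible
Asp40	3.87	-	-	3.1	0.77	4.04	0.17	false	pHtMD: no prediction possible
Asp77	<2.2	2.64	>0.44	3.6	>1.40	2.25	>0.05	false	experimental value is an upper bound
Asp83	<2.2	-	-	-	-	2.72	>0.52	false	bound; pHtMD no prediction; CpHMD high STD (>=5)
Asp95	2.16	3.23	1.07	3.6	1.44	2.69	0.53	true	-
Glu10	2.82	3.83	1.01	4.4	1.58	3.70	0.88	true	-
Glu43	4.32	4.03	0.29	-	-	4.96	0.64	false	CpHMD value dropped for high STD (>=5)
Glu52	3.93	3.77	0.16	4.3	0.37	3.87	0.06	true	-
Glu57	3.49	3.74	0.25	4.3	0.81	4.41	0.92	true	-
Glu67	3.76	3.84	0.08	4.39	0.63	3.61	0.15	true	-
Glu73	3.31	3.84	0.53	4.2	0.89	4.51	1.20	true	-
Glu75	3.26	4.16	0.90	4.0	0.74	3.65	0.39	true	-
Glu101	3.81	3.69	0.12	3.5	0.31	5.25	1.44	true	-
Glu122	3.89	3.27	0.62	3.8	0.09	3.83	0.06	true	-
Glu129	3.75	3.76	0.01	4.28	0.53	4.48	0.73	true	-
Glu135	3.76	3.58	0.18	4.2	0.44	3.27	0.49	true	-
His8	6.50	6.08	0.42	-	-	6.29	0.21	false	His residues not investigated by CpHMD
His121	5.25	5.89	0.64	-	-	6.43	1.18	false	His residues not investigated by CpHMD
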