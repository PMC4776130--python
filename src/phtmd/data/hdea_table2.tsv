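residue	exp_pka	pHtMD	pHtMD_dev	pHREMD_dimer	pHREMD_dimer_dev	pHREMD_monomer	pHREMD_monomer_dev	PROPKA	PROPKA_dev	include	notes
Glu19	4.38	4.07	0.31	4.1	0.28	4.3	0.08	4.77	0.39	true	-
Asp20	3.66	4.11	0.45	3.1	0.56	4.2	0.54	2.46	1.20	true	-
Asp25	3.71	2.75	0.96	3.1	0.61	3.8	0.09	2.82	0.89	true	-
Glu26	4.57	4.37	0.20	4.0	0.57	4.5	0.07	4.74	0.17	true	-
Glu37	-	4.79	-	6.4	-	4.5	-	7.19	-	false	experimental pKa could not be determined
Asp43	3.87	3.78	0.09	3.9	0.03	3.6	0.27	3.59	0.28	true	-
Glu46	4.07	3.87	0.20	3.8	0.27	4.3	0.23	3.94	0.13	true	-
Asp47	4.14	4.18	0.04	4.4	0.26	4.1	0.04	2.96	1.18	true	-
Asp51	3.83	3.72	0.11	3.2	0.63	3.7	0.13	3.71	0.12	true	-
Asp69	3.74	3.64	0.10	3.7	0.04	3.6	0.14	2.92	0.82	true	-
Asp76	3.75	3.45	0.30	3.5	0.25	3.8	0.05	3.23	0.52	true	-
Glu81	4.23	4.11	0.12	4.3	0.07	4.5	0.27	4.65	0.42	true	-
Asp83	3.97	3.59	0.38	3.6	0.37	4.0	0.03	4.07	0.10	true	-
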