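country	n	age_mean	age_sd	sex_Female	sex_Male	sex_Missing	bmi_underweight	bmi_normal	bmi_overweight	bmi_obese	bmi_Missing
Brazil	20	30.1	5.0	18	2	0	0	15	4	1	0
Canada	1269	25.9	5.1	659	610	0	0	973	296	0	0
China	171	43.3	12.4	81	90	0	8	33	32	0	98
Denmark	107	55.4	8.1	73	34	0	0	1	0	0	106
France	465	62.0	10.5	249	216	0	4	228	182	38	13
Germany	70	38.1	8.3	0	70	0	0	29	29	12	0
Italy	40	39.3	13.6	26	14	0	1	26	2	0	11
New Zealand	131	36.9	12.6	82	49	0	0	101	30	0	0
Spain	47	40.9	14.5	31	16	0	0	2	0	0	45
Tanzania	22	36.1	13.3	8	14	0	0	0	0	0	22
UK	273	51.3	13.2	122	149	2	8	180	69	16	0
USA	1822	41.7	16.7	847	965	10	38	1059	495	95	135
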