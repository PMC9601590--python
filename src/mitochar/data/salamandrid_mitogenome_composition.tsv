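# Published whole-mitogenome base compositions (percentages) of 33 salamandrid
# species, keyed by GenBank accession. Skews as printed to two decimals.
species	total_length_bp	T_pct	C_pct	A_pct	G_pct	AT_content_pct	AT_skew	GC_skew	accession
Tylototriton broadoridgus	16265	25.7	26.3	33.6	14.5	59.3	0.13	-0.29	OP598114
Tylototriton gaowangjienensis	16259	25.6	26.3	33.6	14.6	59.2	0.14	-0.29	ON764431
Tylototriton wenxianensis	16265	25.67	26.20	33.62	14.51	59.29	0.13	-0.29	KR733683
Tylototriton kweichowensis	16727	25.64	26.10	33.93	14.33	59.57	0.14	-0.29	KT373904
Tylototriton asperrimus	16161	25.51	26.50	33.26	14.73	58.77	0.13	-0.29	EU880340
Tylototriton pseudoverrucosus	16265	26.06	25.77	33.40	14.77	59.46	0.12	-0.27	KU255458
Tylototriton shanjing	16661	25.41	26.28	34.04	14.27	59.45	0.15	-0.30	KR154461
Tylototriton taliangensis	16265	26.03	25.76	33.42	14.79	59.45	0.12	-0.27	KP979646
Tylototriton verrucosus	16660	25.43	26.31	33.99	14.27	59.42	0.14	-0.30	MF461428
Tylototriton yangi	16648	25.53	26.21	33.99	14.28	59.51	0.14	-0.29	KU297946
Tylototriton ziegleri	16266	25.49	26.38	33.71	14.42	59.20	0.14	-0.29	KY398015
Tylototriton shanorum	17096	25.26	26.40	34.11	14.23	59.37	0.15	-0.30	KU255459
Cynops orphicus	16296	28.91	23.16	32.88	15.05	61.79	0.06	-0.21	EU880312
Echinotriton andersoni	16272	26.47	25.44	34.02	14.07	60.49	0.12	-0.29	EU880314
Euproctus platycephalus	15799	30.14	22.09	34.15	13.61	64.30	0.06	-0.24	EU880317
Calotriton asper	16564	26.47	25.93	32.20	15.41	58.66	0.10	-0.25	EU880307
Ichthyosaura alpestris	16339	27.39	25.05	32.91	14.65	60.30	0.09	-0.26	EU880335
Laotriton laoensis	16361	27.30	24.88	31.80	16.03	59.09	0.08	-0.22	EU880328
Lissotriton vulgaris	16310	28.34	24.74	31.76	15.16	60.10	0.06	-0.24	EU880339
Neurergus kaiseri	16202	27.69	23.97	34.57	13.78	62.26	0.11	-0.27	EU880320
Notophthalmus perstriatus	16336	28.34	23.84	34.08	13.74	62.41	0.09	-0.27	KP013091
Paramesotriton caudopunctatus	15968	28.49	23.57	33.73	14.21	62.22	0.08	-0.25	EU880326
Pleurodeles poireti	16211	27.96	24.46	33.26	14.32	61.22	0.09	-0.26	EU880329
Taricha granulosa	16151	24.99	27.67	31.37	15.97	56.36	0.11	-0.27	EU880333
Lyciasalamandra atifi	16650	29.07	24.13	32.34	14.47	61.41	0.05	-0.25	AF154053
Mertensiella caucasica	17023	29.38	24.54	31.96	14.12	61.34	0.04	-0.27	EU880319
Salamandra atra	15592	30.31	23.35	32.45	13.89	62.76	0.03	-0.25	MF043387
Salamandrina terdigitata	16252	29.59	22.26	34.57	13.59	64.16	0.08	-0.24	EU880332
Chioglossa lusitanica	16417	31.03	22.80	33.01	13.16	64.04	0.03	-0.27	EU880308
Pachytriton brevipes	16240	28.18	23.80	33.15	14.87	61.33	0.08	-0.23	EU880324
Triturus pygmaeus	16442	27.25	25.73	31.83	15.19	59.08	0.08	-0.26	HQ697280
Ommatotriton vittatus	16193	28.80	23.84	32.38	14.98	61.18	0.06	-0.23	EU880338
Batrachuperus pinchonii	16381	32.84	19.65	33.92	13.60	66.75	0.02	-0.18	KX757918
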