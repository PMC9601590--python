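# Published per-region nucleotide compositions and skews of two crocodile-newt
# mitogenomes (GenBank OP598114 = Tylototriton broadoridgus, ON764431 =
# T. gaowangjienensis). Percentages to one decimal, skews to two.
region	accession	size_bp	A_pct	T_pct	C_pct	G_pct	AT_content_pct	AT_skew	GC_skew
D-loop	OP598114	716	28.6	34.9	21.2	15.2	63.5	-0.10	-0.17
D-loop	ON764431	715	29.0	34.5	21.0	15.5	63.5	-0.09	-0.15
12S rRNA	OP598114	928	37.9	19.9	23.9	18.2	57.8	0.31	-0.14
12S rRNA	ON764431	927	38.1	20.1	23.7	18.1	58.2	0.31	-0.13
16S rRNA	OP598114	1563	40.2	23.3	20.3	16.3	63.5	0.27	-0.11
16S rRNA	ON764431	1560	40.1	23.4	20.1	16.4	63.5	0.26	-0.10
tRNAs	OP598114	1537	32.3	30.1	17.7	19.8	62.4	0.04	0.06
tRNAs	ON764431	1537	32.1	30.0	17.9	20.0	62.1	0.03	0.05
PCGs-1st	OP598114	3795	30.0	25.4	25.1	19.4	55.4	0.08	-0.13
PCGs-1st	ON764431	3795	30.3	25.1	25.2	19.3	55.4	0.09	-0.13
PCGs-2nd	OP598114	3794	25.1	33.6	27.9	13.5	58.7	-0.14	-0.35
PCGs-2nd	ON764431	3794	25.0	33.4	28.0	13.5	58.4	-0.14	-0.35
PCGs-3rd	OP598114	3794	37.8	23.0	28.1	11.1	60.8	0.24	-0.43
PCGs-3rd	ON764431	3794	37.0	23.0	28.0	11.4	60.0	0.23	-0.42
PCGs	OP598114	11383	31.0	27.3	27.0	14.7	58.3	0.06	-0.29
PCGs	ON764431	11383	31.0	27.2	27.1	14.8	58.2	0.07	-0.29
Genome	OP598114	16265	33.6	25.7	26.3	14.5	59.3	0.13	-0.29
Genome	ON764431	16259	33.6	25.6	26.3	14.6	59.2	0.14	-0.29
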