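species	lineage	locality	catalogue	field_number	status	sex	SVL	HW	HL	TD	ED	END	NSD	NND	HAL	FORL	HIL	FOTL	FOL	TIBL
ambreensis	LE	Montagne d'Ambre	MNHN 1893.241	NA	HT	F	41.6	12.2	14.2	3.8	4.7	3.7	1.4	3.4	12.3	25.6	71.2	31.6	20.0	22.5
ambreensis	LE1	Irogno Forest	ZSM 80/2016	MSZC 222		F	40.8	12.4	15.2	4.5	5.1	3.9	2.3	4.0	11.7	22.7	62.4	29.1	19.9	20.5
ambreensis	LE1	Irogno Forest	ZSM 83/2016	MSZC 235		F	41.3	12.8	14.9	3.5	5.2	3.4	2.0	3.7	11.3	23.3	64.6	30.3	19.8	21.1
ambreensis	LE1	Makira	ZSM 549/2009	ZCMV 11458		F	40.9	12.7	15.0	4.3	5.9	2.2	1.7	3.2	12.6	25.6	67.5	31.2	20.7	21.7
ambreensis	LE2	Manongarivo	ZSM 807/2003	FG/MV 2002.704		F	42.7	13.3	16.0	4.2	5.4	4.0	2.1	3.6	11.9	26.0	69.1	31.7	20.8	22.0
ambreensis	LE2	Maromiandra	ZSM 561/2014	DRV 6491		F	40.9	12.7	14.9	3.6	5.0	3.1	1.8	3.4	11.6	25.1	67.8	31.8	21.3	22.1
ambreensis	LE3	Tsaratanana	ZSM 634/2001	FG/MV 2001.48		F	39.9	12.6	14.3	3.1	5.0	3.5	1.9	3.3	10.3	23.2	67.6	30.0	19.2	22.3
ambreensis	LE4	Montagne d'Ambre	ZSM 229/2004	FGZC 449		M	36.5	11.7	14.1	4.7	4.9	3.6	1.9	3.3	11.6	24.8	63.6	29.2	21.1	20.0
ambreensis	LE4	Montagne d'Ambre	ZSM 1653/2008	FGZC 3145		M	33.5	11.8	13.4	4.7	5.2	3.4	1.7	2.7	11.5	22.8	59.1	28.5	18.9	18.5
ambreensis	LE1	Bevintagnona Forest	ZSM 78/2016	MSZC 217		M	34.5	11.0	13.8	4.5	4.9	3.4	1.9	3.4	11.0	22.8	60.4	27.6	18.7	18.9
ambreensis	LE1	Irogno Forest	ZSM 81/2016	MSZC 226		M	35.3	11.3	14.0	4.9	5.2	3.0	2.0	3.4	10.7	21.3	57.8	27.4	18.7	18.7
ambreensis	LE2	Manongarivo	ZSM 808/2003	FG/MV 2002.705		M	36.9	11.9	14.6	5.1	5.0	4.1	2.0	3.3	11.6	24.8	67.2	30.7	21.0	20.8
ambreensis	LE3	Tsaratanana	ZSM 635/2001	FG/MV 2001.142		M	35.8	11.5	13.5	4.5	4.7	3.1	1.6	3.1	11.1	23.6	61.1	27.0	17.2	19.8
ambony	HE	Montagne d'Ambre	ZSM 2078/2007	FGZC 1039	HT	F	38.0	12.5	13.1	3.0	4.5	3.7	2.2	3.6	12.3	26.0	66.7	29.8	20.3	20.7
ambony	HE	Montagne d'Ambre	ZSM 492/2000	FG/MV 2000.360	PT	F (SA)	33.0	10.4	11.7	3.2	4.7	3.2	1.5	3.2	9.8	22.6	56.0	25.6	17.2	17.9
ambony	HE	Montagne d'Ambre	ZSM 132/2018	MSZC 754	PT	M	30.8	10.0	11.6	4.1	4.1	3.1	1.6	2.7	9.7	20.8	52.0	23.8	16.4	16.0
ambony	HE	Montagne d'Ambre	ZSM 131/2018	MSZC 633	PT	M	31.6	10.5	12.1	3.7	4.5	2.9	1.9	2.8	10.3	20.5	52.1	24.5	16.3	17.0
ambony	HE	Montagne d'Ambre	ZSM 130/2018	MSZC 500	PT	M	32.5	10.6	12.3	5.2	5.0	3.1	1.4	2.8	10.8	22.6	57.8	25.9	17.2	17.7
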