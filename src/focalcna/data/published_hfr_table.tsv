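# High-frequency regions (HFRs) of recurrent focal copy-number aberrations in 26 osteosarcomas,
# with the gene(s) located within or overlapping each HFR. Coordinates are 1-based bp on hg18
# (NCBI36/Ensembl 54) as originally printed. Focal_*: number of samples with a focal (<=3 Mb)
# aberration of that direction covering the HFR; Total_*: number of samples with any aberration
# of that direction containing the HFR.
Chrom	Start	End	Size_kb	Focal_gain	Focal_loss	Total_gain	Total_loss	Genes
1	68394382	68461186	67	2	0	10	0	GPR177
1	166259174	166263398	4	2	0	8	0	IQWD1
1	145961855	146262362	301	2	1	8	1	FAM108A2,NBPF11
2	51022554	51022614	0.06	2	0	3	1	NRXN1
2	153790092	154905667	1116	2	0	3	1	RPRM,GALNT13
2	212844992	212863839	19	1	3	1	5	ERBB4
2	237017756	237067914	50	0	3	1	8	IQCA1
3	38177003	38246945	70	1	2	1	6	OXSR1
3	57426028	57504090	78	0	2	0	8	DNAH12L
3	59855182	59891414	36	0	2	0	9	FHIT
3	60208127	60420353	212	0	2	0	9	FHIT
3	24260772	24290280	30	0	3	0	5	THRB
3	32341229	32364439	23	0	3	0	6	CMTM8
4	90072621	90081252	9	0	2	1	3	FAM13A1
4	183476755	184028352	552	0	2	1	7	ODZ3
4	73484965	73485361	0.396	0	15	0	17	ADAMTS3
5	170214294	170645196	431	1	2	1	5	RANBP17
5	55470977	55502030	31	0	2	1	10	ANKRD55
5	110611609	110683366	72	0	2	0	8	CAMK4
5	135294758	135330960	36	0	2	0	8	FBXL21,LECT2
5	158336707	158375568	39	0	4	0	7	EBF1
5	58765648	58766102	0.454	0	5	0	12	PDE4D
5	80023854	80024518	0.664	0	11	0	14	MSH3
6	44998738	45119343	121	5	0	11	0	SUPT3H
6	13965760	14255124	289	2	1	4	1	CD83,RNF182
6	14051934	14103151	51	2	1	4	1	RNF182
6	86262042	86335470	73	0	3	0	11	SNX14,NT5E
6	110510873	110539046	28	0	4	0	12	WASF1
7	57480106	57659360	179	2	0	3	1	ZNF716
7	63149422	63486197	337	2	0	3	1	ZNF679,ZNF735
7	943615	954205	11	1	2	1	3	ADAP1
7	15536047	15536441	0.394	0	6	0	7	TMEM195
8	128437695	130578879	2141	4	1	14	1	TMEM75,MYC,POU5F1P1
8	124855221	124894704	39	3	0	17	0	FAM91A1
8	132030642	132421393	391	2	0	16	0	ADCY8
8	64257961	64390486	133	2	1	12	1	YTHDF3
8	145064850	145118710	54	2	1	11	1	PLEC1
8	25130171	25130291	0.12	1	14	1	15	DOCK5
9	3339487	3417226	78	1	2	1	8	RFX3
9	71289871	71308842	19	0	2	0	5	APBA1
9	87357661	87432833	75	0	3	0	5	AGTPBP1
9	33230225	33242111	12	0	8	0	12	SPINK4
10	115580402	115675237	95	1	2	1	11	NHLRC2,DCLRE1A
10	25604754	25659341	55	1	3	1	15	GPR158
10	15898437	15929438	31	0	2	0	16	C10orf97
10	38082301	38147982	66	0	2	1	11	ZNF248
10	71648150	71656573	8	0	2	0	12	PPA1
10	123566469	123752493	186	0	2	1	13	TACC2,NSMCE4A,ATE1
10	89716166	89756083	40	0	3	0	14	PTEN
10	72166137	72172267	6	0	4	0	12	ADAMTS14
11	20922810	20971401	49	0	2	0	3	NELL1
11	92517181	92571937	55	0	2	0	5	SLC36A4
11	104441220	104484303	43	0	2	0	4	CARD17
11	47391562	47453463	62	0	3	0	3	CUGBP1,RAPSN,PSMC3,SLC39A13
11	102486510	102663548	177	0	4	0	5	DYNC2H1
12	51710169	51719305	9	0	2	0	5	EIF4B
12	91645948	91679726	34	0	2	1	5	PLEKHG7
12	18413696	18414167	0.471	0	4	1	7	PIK3C2G
13	92502207	93946439	1444	1	2	1	12	DCT,GPC6
13	34399863	34517051	117	0	5	0	14	NBEA
14	59138607	59161895	23	2	1	5	1	RTN1
14	69961223	69998909	38	0	6	0	6	ADAM21,ADAM21P
15	59943982	60046989	103	0	2	1	3	VPS13C
16	87557619	87557679	0.06	1	2	1	8	CBFA2T3
16	87527215	87549395	22	1	3	1	9	CBFA2T3
16	71734726	71798103	63	0	2	0	6	C16orf47
16	45728834	45887805	159	0	4	0	6	ITFG1,NETO2
17	37018570	37057586	39	0	4	1	7	KRT42P,KRT17,KRT16
19	33996261	34984966	989	4	1	12	1	C19orf12,PLEKHF1,POP4,VSTM2B,UQCRFS1,UQCRFSL1
19	532070	556653	25	0	4	1	4	HCN2,BSG
19	60711906	60737394	25	0	4	1	6	SBK2
X	33147645	33243866	96	1	6	1	15	DMD
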