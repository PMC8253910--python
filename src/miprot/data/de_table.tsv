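Protein identifier	Pig gene	Human gene	Number of peptides identified	Time point of significance	Increased expression in	ANOVA q (treatment*time)
XP_005657428.1	AP1B1	AP1B1	45	30 min	SCS	0.006228671
XP_005656554.1	BOD1L1	BOD1L1	2	30 min	NEVKP	0.000195143
NP_999577.1	CYP1A1	CYP1A1	7	30 min	NEVKP	0.041408521
F1SPF6	RUVBL1	RUVBL1	11	30 min	SCS	0.04744904
XP_005674249.1	ABHD10	ABHD10	11	POD3	NEVKP	0.04502203
F1SRC5	ACO2	ACO2	53	POD3	NEVKP	0.028569884
XP_005660584.1	AIF1L	AIF1L	5	POD3	NEVKP	0.024400643
XP_003121238.3	ALDH8A1	ALDH8A1	18	POD3	NEVKP	0.036141682
F1SAM7	AMN	AMN	13	POD3	NEVKP	0.000421914
XP_005660857.1	ASRGL1	ASRGL1	12	POD3	NEVKP	0.022052418
F1SAX3	ATP1A1	ATP1A1	52	POD3	NEVKP	0.000824428
Q95339	ATP5MF	ATP5MF	3	POD3	NEVKP	0.014481044
F1SLE5	ATP6V1B1	ATP6V1B1	24	POD3	NEVKP	0.001670187
XP_003123717.3	CDHR2	CDHR2	15	POD3	NEVKP	0.018134312
XP_005659624.1	CGNL1	CGNL1	8	POD3	NEVKP	0.040245498
F1SPI0	CHCHD4	CHCHD4	5	POD3	NEVKP	0.026300633
I3LA22	CLPTM1L	CLPTM1L	4	POD3	SCS	0.020237625
I3LER5	COX4I1	COX4I1	11	POD3	NEVKP	0.012604806
NP_001233172.1	CPT2	CPT2	36	POD3	NEVKP	0.012494487
XP_005654692.1	CTTN	CTTN	9	POD3	NEVKP	0.020549915
I3LF61	CYP4F8	CYP4F8	15	POD3	NEVKP	0.014133684
XP_003125985.3	DDAH1	DDAH1	14	POD3	NEVKP	0.003389761
F1RXF3	DECR1	DECR1	16	POD3	NEVKP	0.048295598
F1SM86	EPB41L3	EPB41L3	27	POD3	NEVKP	0.017804864
XP_005665495.1	EPS15	EPS15	24	POD3	NEVKP	0.005103183
Q6UAQ8	ETFB	ETFB	17	POD3	NEVKP	0.004187732
P16549	FMO1	FMO1	26	POD3	NEVKP	0.016340051
F1S006	FN3K	FN3K	5	POD3	NEVKP	0.018266499
I3L677	G6PD	G6PD	18	POD3	SCS	5.18292E-05
F1STB6	GBA2	GBA2	19	POD3	NEVKP	0.036355338
F1S5J5	HABP2	HABP2	2	POD3	NEVKP	0.014013642
I3LTZ3	HGD	HGD	14	POD3	NEVKP	0.030812863
NP_001177098.1	HOGA1	HOGA1	12	POD3	NEVKP	0.022664251
Q06AT0	HPCAL1	HPCAL1	4	POD3	SCS	0.001994047
I3L8C5	HSPA12A	HSPA12A	31	POD3	NEVKP	0.003810733
NP_001230836.1	HSPA8	HSPA8	35	POD3	SCS	0.017815849
I3LAT6	IARS	IARS	4	POD3	NEVKP	0.000583668
F1SSR4	IVD	IVD	20	POD3	NEVKP	0.024332153
F1RU12	LACTB2	LACTB2	17	POD3	NEVKP	0.012593529
NP_001116606.1	LIPA	LIPA	8	POD3	SCS	0.003820522
I3LCC2	MARS	MARS	14	POD3	SCS	0.002446129
K7GM47	MECP2	MECP2	13	POD3	NEVKP	0.012373323
Q2EN77	MGST3	MGST3	5	POD3	NEVKP	0.031301414
F1SD56	MISP3	MISP3	11	POD3	NEVKP	0.03029979
K7GMJ2	MME	MME	43	POD3	NEVKP	0.002598281
F1SR71	MOGAT1	MOGAT1	5	POD3	NEVKP	0.009582449
XP_003355117.1	MPC2	MPC2	7	POD3	NEVKP	0.024029416
I3LMQ8	NDUFAF7	NDUFAF7	13	POD3	SCS	0.00415399
XP_005665310.1	PABPC4	PABPC4	18	POD3	SCS	0.004696561
XP_003123959.1	PDLIM4	PDLIM4	10	POD3	NEVKP	0.021981244
XP_005674442.1	PIP4K2C	PIP4K2C	8	POD3	NEVKP	0.042699072
XP_005668225.1	PLXDC2	PLXDC2	5	POD3	NEVKP	0.042880002
F2Z5L7	PSMA1	PSMA1	13	POD3	SCS	0.001007071
F1S4R1	RMDN2	RMDN2	5	POD3	NEVKP	0.02241622
F1RK77	ROGDI	ROGDI	2	POD3	NEVKP	0.024939309
F1RTJ9	RPL21	RPL21	5	POD3	SCS	0.031890423
F2Z5C7	RPS3A	RPS3A	17	POD3	SCS	0.025650357
F1RHN7	SEPT5	SEPT5	3	POD3	NEVKP	0.038733081
I3L854	SLC22A10L	SLC22A10	4	POD3	NEVKP	0.00197433
F1S5K2	SLC3A1	SLC3A1	21	POD3	NEVKP	0.007752504
B8XH67	SLC9A3R1	SLC9A3R1	26	POD3	NEVKP	0.005064438
F1SS29	SRP14	SRP14	2	POD3	SCS	5.56947E-05
XP_005662658.1	SRSF7	SRSF7	7	POD3	SCS	0.028156373
C5HGF3	TMCO1	TMCO1	2	POD3	SCS	0.005807246
XP_005672544.1	TRAPPC13	TRAPPC13	4	POD3	NEVKP	0.015800783
F1RK61	UFD1	UFD1	6	POD3	NEVKP	7.988E-05
XP_005664372.1	USP10L	USP10	9	POD3	NEVKP	0.003800781
XP_005672359.1	USP40	USP40	14	POD3	NEVKP	0.005711515
F1SK83	WASHC1	WASHC1	13	POD3	NEVKP	0.017684621
F1SRE0	XRCC6	XRCC6	12	POD3	SCS	6.28153E-05
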