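# Transcribed clinical reference cohort: 45 dried-blood-spot samples from 43
# patients with inborn errors of immunity; causative-protein level in
# %beta-actin units. BLD = below detection limit. presymptomatic marks samples
# drawn before disease onset (stored public-screening cards).
patient	sample	age_months	disease	gene	protein_name	allele1	allele2	value	presymptomatic
1	1	3	FHL type 3	UNC13D	Munc13-4	c.1596+1G>C	c.1255delC, p.Leu419Serfs*23	0.143	no
2	2	266	FHL type 3	UNC13D	Munc13-4	c.1596+1G>C	c.1240C>T, p.Arg414Cys	0.192	no
3	3	0	FHL type 3	UNC13D	Munc13-4	c.1596+1G>C	c.118-308C>T	0.357	yes
4	4	0	FHL type 3	UNC13D	Munc13-4	c.1596+1G>C	c.1545-2A>G	0.182	yes
5	5	1	FHL type 3	UNC13D	Munc13-4	c.754-1G>C	c.1596+1G>C	0.132	no
5	6	0	FHL type 3	UNC13D	Munc13-4	c.754-1G>C	c.1596+1G>C	0.120	yes
6	7	4	FHL type 3	UNC13D	Munc13-4	c.1849-1G>C	c.1849-1G>C	0.270	no
6	8	0	FHL type 3	UNC13D	Munc13-4	c.1849-1G>C	c.1849-1G>C	0.360	yes
7	9	0	FHL type 3	UNC13D	Munc13-4	c.1596+1G>C	c.1596+1G>C	0.280	no
8	10	0	FHL type 3	UNC13D	Munc13-4	c.754-1G>C	c.1596+1G>C	0.190	yes
9	11	3	FHL type 5	STXBP2	Munc18-2	c.1197delC, p.Ala400Profs*18	c.1430C>T, p.Pro477Leu	1.120	no
10	12	1	FHL type 2	PRF1	perforin	c.658G>A, p.Gly220Ser	c.1090_1091delCT, p.Leu364Glufs*93	0.290	no
11	13	2	FHL type 2	PRF1	perforin	c.853_855delAAG, p.Lys285del	c.1090_1091delCT, p.Leu364Glufs*93	0.330	no
12	14	9	HPS type 2	AP3B1	AP3B1	c.2546T>A, p.Leu849X	c.1122_1123insAG, p.Phe375Serfs*11	0.183	no
13	15	102	HPS type 2	AP3B1	AP3B1	c.364C>T, p.Arg122X	c.2810-1G>T	1.080	no
14	16	38	HPS type 2	AP3B1	AP3B1	c.2546T>A, p.Leu849X	c.188T>A, p.Met63Lys	0.439	no
15	17	19	CGD	CYBB	p91-phox	c.1528_1529delTT, p.Leu510Valfs*8	NA	0.010	no
16	18	318	CGD	CYBB	p91-phox	c.121dupT, p.Tyr41Leufs*62	NA	0.020	no
17	19	87	CGD	CYBB	p91-phox	c.1031C>T, p.Ser344Phe	NA	0.010	no
18	20	62	CGD	CYBB	p91-phox	c.252G>A, p.Ala84Ala	NA	0.024	no
19	21	48	CGD	CYBB	p91-phox	c.810G>A, p.Trp270X	NA	0.015	no
20	22	105	CGD	CYBB	p91-phox	c.271C>T, p.Arg91X	NA	0.058	no
21	23	213	CGD	CYBA	p22-phox	c.70G>A, p.Gly24Arg	c.7C>T, p.Gln3X	BLD	no
22	24	132	CGD	NCF1	p47-phox	c.75_76delGT, p.Tyr26Hisfs*26	c.75_76delGT, p.Tyr26Hisfs*26	0.010	no
23	25	12	WAS	WAS	WASP	c.777+3_777+6delGAGT	NA	BLD	no
24	26	4	WAS	WAS	WASP	c.132+1G>T	NA	BLD	no
25	27	70	WAS	WAS	WASP	c.982delC, p.Arg328Glyfs*117	NA	0.011	no
26	28	226	WAS	WAS	WASP	c.961C>T, p.Arg321X	NA	BLD	no
27	29	6	WAS	WAS	WASP	c.1075C>A, p.Pro359Thr	NA	BLD	no
28	30	26	XLA	BTK	BTK	c.1574G>A, p.Arg525Gln	NA	0.005	no
29	31	36	XLA	BTK	BTK	c.1856C>T, p.Pro619Leu	NA	0.004	no
30	32	20	XLA	BTK	BTK	c.862C>T, p.Arg288Trp	NA	0.017	no
31	33	386	XLA	BTK	BTK	c.1921C>T, p.Arg641Cys	NA	0.029	no
32	34	113	XLA	BTK	BTK	c.902-904delAAG, p.Glu301del	NA	0.055	no
33	35	456	XLA	BTK	BTK	c.95T>C, p.Leu32Ser	NA	0.002	no
34	36	255	XLA	BTK	BTK	c.1856C>T, p.Pro619Leu	NA	0.035	no
35	37	0	SCID	ADA	ADA1	c.218+2T>G	c.218+2T>G	0.040	no
36	38	3	SCID	ADA	ADA1	c.218+2T>G	c.632G>A, p.Arg211His	0.108	no
37	39	0	X-SCID	IL2RG	IL2Rgamma	c.865C>T, p.Arg289X	NA	BLD	no
38	40	2	X-SCID	IL2RG	IL2Rgamma	c.374A>G, p.Tyr125Cys	NA	BLD	no
39	41	0	CHS	LYST	LYST	c.1673dupT, p.Leu558Phefs*22	c.5506C>T, p.Arg1836X	0.003	yes
40	42	213	CHS	LYST	LYST	c.3393+1G>T	c.3393+1G>T	0.016	no
41	43	373	CHS	LYST	LYST	c.5541_5542delAA, p.Arg1848Serfs*3	unknown	0.012	no
42	44	346	CHS	LYST	LYST	c.5541_5542delAA, p.Arg1848Serfs*3	unknown	0.009	no
43	45	346	CHS	LYST	LYST	c.5541_5542delAA, p.Arg1848Serfs*3	unknown	0.026	no
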