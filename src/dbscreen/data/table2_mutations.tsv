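# Transcribed clinical mutation table: one row per allele, with the
# variant-effect annotations used to predict protein loss (NMD probability for
# truncating alleles; FoldX total-energy change, kcal/mol, for missense
# alleles) and the observed protein-loss call from the quantification data.
# ND = observed loss not determined (protein undetectable in all samples).
disease	gene	allele	consequence	pathogenicity	nmd_annotation	ddg	observed_loss
FHL type 3	UNC13D	c.1240C>T, p.Arg414Cys	Missense mutation	Deleterious (0.856)		3.28	Yes
FHL type 3	UNC13D	c.1255delC, p.Leu419Serfs*23	Frameshift		NMD		Yes
FHL type 3	UNC13D	c.1596+1G>C	Splicing anomaly				Yes
FHL type 3	UNC13D	c.118-308C>T	Transcriptional dysregulation	Predicted benign			Yes
FHL type 3	UNC13D	c.754-1G>C	Splicing anomaly		Exon skip 105 bp		Yes
FHL type 3	UNC13D	c.1849-1G>C	Splicing anomaly		Exon skip 144 bp		Yes
FHL type 3	UNC13D	c.1545-2A>G	Splicing anomaly		Exon skip 54 bp		Yes
FHL type 5	STXBP2	c.1430C>T, p.Pro477Leu	Missense mutation	Deleterious (0.857)		4.29	Yes
FHL type 5	STXBP2	c.1197delC, p.Ala400Profs*18	Frameshift		NMD		Yes
FHL type 2	PRF1	c.658G>A, p.Gly220Ser	Missense mutation	Deleterious (0.98)		14.1	No
FHL type 2	PRF1	c.853_855delAAG, p.Lys285del	Deletion	benign			No
FHL type 2	PRF1	c.1090_1091delCT, p.Leu364Glufs*93	Frameshift		NMD escaping		No
HPS type 2	AP3B1	c.188T>A, p.Met63Lys	Missense mutation	Uncertain (0.67)		5.13	No
HPS type 2	AP3B1	c.1122_1123insAG, p.Phe375Serfs*11	Frameshift		NMD		Yes
HPS type 2	AP3B1	c.2546T>A, p.Leu849X	Nonsense mutation		NMD		Yes
HPS type 2	AP3B1	c.364C>T, p.Arg122X	Nonsense mutation		NMD		Reduced but detectable
HPS type 2	AP3B1	c.2810-1G>T	Splicing anomaly		Exon skip 85 bp		Reduced but detectable
CGD	CYBB	c.1031C>T, p.Ser344Phe	Missense mutation	Deleterious (0.99)		12.5	Yes
CGD	CYBB	c.1528_1529delTT, p.Leu510Valfs*8	Frameshift		NMD		Yes
CGD	CYBB	c.121dupT, p.Tyr41Leufs*62	Frameshift		NMD		Yes
CGD	CYBB	c.810G>A, p.Trp270X	Nonsense mutation		NMD		Yes
CGD	CYBB	c.271C>T, p.Arg91X	Nonsense mutation		NMD		Yes
CGD	CYBB	c.252G>A, p.Ala84Ala	Synonymous splice	Deleterious (0.80)	splicing anomaly		Yes
CGD	CYBA	c.70G>A, p.Gly24Arg	Missense mutation	Deleterious (0.87)		6.54	Yes
CGD	CYBA	c.7C>T, p.Gln3X	Nonsense mutation		NMD escaping		Yes
CGD	NCF1	c.75_76delGT, p.Tyr26Hisfs*26	Frameshift		NMD escaping		Reduced but detectable
WAS	WAS	c.1075C>A, p.Pro359Thr	Missense mutation	Uncertain (0.54)		0.37	Yes
WAS	WAS	c.982delC, p.Arg328Glyfs*117	Frameshift		NMD		Reduced but detectable
WAS	WAS	c.961C>T, p.Arg321X	Nonsense mutation		NMD		Yes
WAS	WAS	c.777+3_777+6delGAGT	Splicing anomaly				Yes
WAS	WAS	c.132+1G>T	Splicing anomaly				Yes
XLA	BTK	c.95T>C, p.Leu32Ser	Missense mutation	Deleterious (0.99)		5.26	Yes
XLA	BTK	c.862C>T, p.Arg288Trp	Missense mutation	Deleterious (0.88)		1.81	Yes
XLA	BTK	c.1574G>A, p.Arg525Gln	Missense mutation	Deleterious (0.88)		0.02	Yes
XLA	BTK	c.1856C>T, p.Pro619Leu	Missense mutation	Deleterious (0.87)		6.19	Yes
XLA	BTK	c.1921C>T, p.Arg641Cys	Missense mutation	Deleterious (0.88)		2.95	Yes
XLA	BTK	c.902-904delAAG, p.Glu301del	Deletion				Yes
SCID	ADA	c.632G>A, p.Arg211His	Missense mutation	Deleterious (0.99)		9.20	No
SCID	ADA	c.218+2T>G	Splicing anomaly				No
X-SCID	IL2RG	c.374A>G, p.Tyr125Cys	Missense mutation	Deleterious (0.86)		3.36	ND
X-SCID	IL2RG	c.865C>T, p.Arg289X	Nonsense mutation		NMD escaping		ND
CHS	LYST	c.5506C>T, p.Arg1836X	Nonsense mutation		NMD		Reduced but detectable
CHS	LYST	c.1673dupT, p.Leu558Phefs*22	Frameshift		NMD		Reduced but detectable
CHS	LYST	c.5541_5542delAA, p.Arg1848Serfs*3	Frameshift		NMD		Reduced but detectable
CHS	LYST	c.3393+1G>T	Splicing anomaly				No
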