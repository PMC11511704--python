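# Transcribed healthy reference statistics (%beta-actin) per causative
# protein: mean, sample SD and minimum over 40 healthy newborns and 8 healthy
# adults. NA = the protein was below detection in every reference sample, so
# no reference interval exists.
gene	protein_name	group	mean	sd	min	n
UNC13D	Munc13-4	healthy_newborn	10.9	2.6	5.9	40
UNC13D	Munc13-4	healthy_adult	8.2	3.2	3.3	8
STXBP2	Munc18-2	healthy_newborn	10.9	2.1	4.0	40
STXBP2	Munc18-2	healthy_adult	7.8	2.1	4.8	8
PRF1	perforin	healthy_newborn	0.33	0.28	0.28	40
PRF1	perforin	healthy_adult	0.30	0.35	0.044	8
AP3B1	AP3B1	healthy_newborn	2.93	0.88	1.08	40
AP3B1	AP3B1	healthy_adult	0.91	0.25	0.58	8
CYBB	p91-phox	healthy_newborn	2.63	1.36	0.72	40
CYBB	p91-phox	healthy_adult	0.78	0.51	0.30	8
CYBA	p22-phox	healthy_newborn	7.1	4.1	1.9	40
CYBA	p22-phox	healthy_adult	3.5	1.4	1.7	8
NCF1	p47-phox	healthy_newborn	0.18	0.099	0.025	40
NCF1	p47-phox	healthy_adult	0.10	0.062	0.057	8
WAS	WASP	healthy_newborn	0.098	0.039	0.022	40
WAS	WASP	healthy_adult	0.056	0.025	0.024	8
BTK	BTK	healthy_newborn	0.60	0.16	0.25	40
BTK	BTK	healthy_adult	0.39	0.17	0.26	8
ADA	ADA1	healthy_newborn	0.075	0.054	0.014	40
ADA	ADA1	healthy_adult	0.18	0.096	0.047	8
IL2RG	IL2Rgamma	healthy_newborn	NA	NA	NA	40
IL2RG	IL2Rgamma	healthy_adult	NA	NA	NA	8
LYST	LYST	healthy_newborn	0.056	0.035	0.01	40
LYST	LYST	healthy_adult	0.025	0.018	0.0075	8
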