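probeID	Gene	ProbeChr	Probe_bp	topSNP	topSNP_chr	topSNP_bp	Freq	b_SMR	se_SMR	p_SMR	FDR_BH
ENSG00000091127	PUS7	7	105121411	rs150681721	7	105050546	0.0755467	0.788793	0.169944	3.4592E-06	5.7654E-06
ENSG00000111801	BTN3A3	6	26447171	rs989134	6	26336224	0.545726	0.244763	0.05325	4.2968E-06	6.7137E-06
ENSG00000112343	TRIM38	6	25974189	rs989134	6	26336224	0.545726	0.268453	0.0605902	9.3958E-06	1.1745E-05
ENSG00000112763	BTN2A1	6	26467499	rs989134	6	26336224	0.545726	-0.356753	0.0909864	8.82E-05	8.82E-05
ENSG00000124508	BTN2A2	6	26389213	rs989134	6	26336224	0.545726	-0.251219	0.0551958	5.3289E-06	7.8366E-06
ENSG00000157578	LCA5L	21	40797750	rs2735307	21	40713358	0.404573	0.113251	0.0205662	3.6572E-08	1.9033E-07
ENSG00000158373	H2BC5	6	26164963	rs989134	6	26336224	0.545726	-0.0705567	0.0128304	3.8156E-08	1.9033E-07
ENSG00000158406	H4C8	6	26283522	rs989134	6	26336224	0.545726	-0.0403858	0.0072471	2.5085E-08	1.9033E-07
ENSG00000168274		6	26217438	rs989134	6	26336224	0.545726	-0.26184	0.0583014	7.0842E-06	9.3666E-06
ENSG00000168827	GFM1	3	158386215	rs7629432	3	157895285	0.389662	-0.6401630	0.132339	1.3163E-06	2.5313E-06
ENSG00000174891	RSRC1	3	158043581	rs7629432	3	157895285	0.389662	-0.191757	0.0354961	6.5835E-08	2.1133E-07
ENSG00000182093	GET1	21	40776312	rs2735307	21	40713358	0.404573	0.0394364	0.00682604	7.5886E-09	9.4858E-08
ENSG00000182952	HMGN4	6	26542557	rs989134	6	26336224	0.545726	-0.134601	0.0276464	1.1235E-06	2.3407E-06
ENSG00000183527	PSMG1	21	40551236	rs2735307	21	40713358	0.404573	0.228506	0.0476737	1.6421E-06	2.9323E-06
ENSG00000185658	BRWD1	21	40624793	rs2735307	21	40713358	0.404573	-0.200483	0.040257	6.3564E-07	1.4446E-06
ENSG00000186470	BTN3A2	6	26371966	rs989134	6	26336224	0.545726	0.0804045	0.0147063	4.5678E-08	1.9033E-07
ENSG00000196966		6	26225613	rs989134	6	26336224	0.545726	0.239263	0.0555148	1.6333E-05	1.7754E-05
ENSG00000197846		6	26200345	rs989134	6	26336224	0.545726	-0.0977073	0.0181028	6.7627E-08	2.1133E-07
ENSG00000197903	H2BC12	6	27110346	rs989134	6	26336224	0.545726	0.262004	0.0583513	7.1186E-06	9.3666E-06
ENSG00000198518		6	26205562	rs989134	6	26336224	0.545726	-0.115743	0.0217319	1.0042E-07	2.7893E-07
ENSG00000205581	HMGN1	21	40717907	rs2735307	21	40713358	0.404573	-0.0313818	0.00542019	7.0471E-09	9.4858E-08
ENSG00000217275		6	26202633	rs989134	6	26336224	0.545726	-0.117888	0.0269871	1.2521E-05	1.4906E-05
ENSG00000228223	HCG11	6	26524441	rs989134	6	26336224	0.545726	0.15061	0.0371111	4.9422E-05	5.1482E-05
ENSG00000228223	HCG11	6	26524441	rs989134	6	26336224	0.545726	0.15061	0.0371111	4.9422E-05	5.1482E-05
ENSG00000241549	GUSBP2	6	26881798	rs989134	6	26336224	0.545726	-0.119927	0.0276434	1.4354E-05	1.6311E-05
ENSG00000261584		6	26687330	rs989134	6	26336224	0.545726	-0.0686969	0.0135111	3.6861E-07	9.2152E-07
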