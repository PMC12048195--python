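patient_id	phe_pretreatment	clinical_type	sex	birth_year	consanguinity	variant	depth	allele_fraction	acmg_codes	acmg_class	apv	gpv	biopku_type	biopku_support
1	1074	mPKU	F	1997	none	NC_000012.12(NM_000277.3):c.782G > A	85	0.56	PM1,PM2,PM3,PM5,PP2,PP3,PS3	pathogenic	NA	NA	NA	NA
2	2400	cPKU	F	2002	none	NC_000012.12(NM_000277.3):c.781C > T	316	0.40	PVS1,PM2,PM3,PS3	pathogenic	0	0	classic	12/12
2	2400	cPKU	F	2002	none	NC_000012.12(NM_000277.3):c.473G > A	1729	0.45	PM1,PM2,PM3,PM5,PP2,PP3,PS3	pathogenic	0	0	classic	12/12
3	1440	cPKU	F	2002	none	NC_000012.12(NM_000277.3):c.781C > T	93	0.38	PVS1,PM2,PM3,PS3	pathogenic	0	0	classic	12/12
3	1440	cPKU	F	2002	none	NC_000012.12(NM_000277.3):c.473G > A	252	0.42	PM1,PM2,PM3,PM5,PP2,PP3,PS3	pathogenic	0	0	classic	12/12
4	1560	cPKU	M	1998	none	NC_000012.12(NM_000277.3):c.1066-11G > A	1400	0.62	PM2,PM3,PS3	pathogenic	0	0	classic	673/681
5	1464	cPKU	M	1998	none	NC_000012.12(NM_000277.3):c.1066-11G > A	594	0.60	PM2,PM3,PS3	pathogenic	0	0	classic	673/681
6	2058	cPKU	F	2002	none	NC_000012.12(NM_000277.3):c.1066-11G > A	897	0.62	PM2,PM3,PS3	pathogenic	0	0	classic	673/681
7	684	mPKU	M	1998	none	NC_000012.12(NM_000277.3):c.464G > A	1713	0.50	PM1,PM2,PM3,PM5,PP1,PP2,PP3,PS3	pathogenic	10	9.7	mild_HPA	3/3
7	684	mPKU	M	1998	none	NC_000012.12(NM_000277.3):c.898G > T	411	0.67	PM1,PM2,PM3,PM5,PP2,PP3,PS3	pathogenic	9.7	9.7	mild_HPA	3/3
8	1776	cPKU	M	1993	third_degree_cousin	NC_000012.12(NM_000277.3):c.781C > T	257	0.38	PVS1,PM2,PM3,PS3	pathogenic	NA	NA	classic	5/7
8	1776	cPKU	M	1993	third_degree_cousin	NC_000012.12(NM_000277.3):c.143 T > C	85	0.31	PM1,PM2,PM3,PP1,PP2,PP3,PS3	pathogenic	NA	NA	classic	5/7
9	1200	cPKU	M	1992	none	NC_000012.12(NM_000277.3):c.782G > A	146	0.32	PM1,PM2,PM3,PM5,PP2,PP3,PS3	pathogenic	1.5	1.5	classic	93/123
9	1200	cPKU	M	1992	none	NC_000012.12(NM_000277.3):c.1066-11G > A	786	0.33	PM2,PM3,PS3	pathogenic	0	1.5	classic	93/123
10	1050	cPKU	F	1996	none	NC_000012.12(NM_000277.3):c.782G > A	454	0.29	PM1,PM2,PM3,PM5,PP2,PP3,PS3	pathogenic	1.5	2	classic	15/61
10	1050	cPKU	F	1996	none	NC_000012.12(NM_000277.3):c.143 T > C	513	0.36	PM1,PM2,PM3,PP1,PP2,PP3,PS3	pathogenic	2	2	classic	15/61
11	guthrie_gt_8mgdl	cPKU	M	1993	yes_unknown_degree	NC_000012.12(NM_000277.3):c.754C > T	222	0.72	PM1,PM2,PM3,PM5,PP1,PP2,PP3,PS3	pathogenic	0	0	classic	126/128
12	1122	cPKU	M	2001	first_degree_cousin	NC_000012.12(NM_000277.3):c.782G > A	172	0.62	PM1,PM2,PM3,PM5,PP2,PP3,PS3	pathogenic	1.5	1.5	classic	184/381
13	1429	cPKU	F	1993	yes_unknown_degree	NC_000012.12(NM_000277.3):c.1066-11G > A	570	0.60	PM2,PM3,PS3	pathogenic	0	0	classic	673/681
14	1380	cPKU	M	1986	first_degree_cousin	NC_000012.12(NM_000277.3):c.842C > T	160	0.89	PM2,PM3,PM5,PP2,PP3,PS3	pathogenic	0	0	classic	207/208
15	2400	cPKU	M	2001	first_degree_cousin	NC_000012.12(NM_000277.3):c.1066-11G > A	570	0.76	PM2,PM3,PS3	pathogenic	0	0	classic	673/681
16	1500	cPKU	M	2001	first_degree_cousin	NC_000012.12(NM_000277.3):c.331C > T	1920	0.80	PVS1,PM2,PM3	pathogenic	0	0	classic	28/29
17	1800	cPKU	M	2002	first_degree_cousin	NC_000012.12(NM_000277.3):c.1159 T > C	321	0.87	PM1,PM2,PM3,PM5,PP2,PP3	pathogenic	0	0	classic	2/2
18	900	cPKU	F	unknown	unknown	NC_000012.12(NM_000277.3):c.592_613del	202	0.24	PVS1,PM2,PM3	pathogenic	NA	NA	NA	NA
18	900	cPKU	F	unknown	unknown	NC_000012.12(NM_000277.3):c.1169A > G	1383	0.40	PM1,PM2,PM3,PP2,PP3,PS3	pathogenic	NA	NA	NA	NA
19	960	cPKU	M	1996	first_degree_cousin	NC_000012.12(NM_000277.3):c.842C > T	180	0.87	PM2,PM3,PM5,PP2,PP3,PS3	pathogenic	0	0	classic	207/208
20	1350	mPKU	M	1999	none	NC_000012.12(NM_000277.3):c.1169A > G	1120	0.69	PM1,PM2,PM3,PP2,PP3,PS3	pathogenic	6.8	6.8	mild_HPA	21/29
21	1804	cPKU	F	2016	unknown	NC_000012.12(NM_000277.3):c.168+5G > C	248	0.48	PM2,PM3,PP3	pathogenic	0	0	classic	27/27
21	1804	cPKU	F	2016	unknown	NC_000012.12(NM_000277.3):c.1066-11G > A	663	0.37	PM2,PM3,PS3	pathogenic	0	0	classic	27/27
22	1009	cPKU	M	2020	unknown	NC_000012.12(NM_000277.3):c.168+5G > C	55	0.55	PM2,PM3,PP3	pathogenic	0	0	classic	27/27
22	1009	cPKU	M	2020	unknown	NC_000012.12(NM_000277.3):c.1066-11G > A	458	0.40	PM2,PM3,PS3	pathogenic	0	0	classic	27/27
23	1612	cPKU	F	2023	unknown	NC_000012.12(NM_000277.3):c.1222C > T	1128	0.44	PM1,PM2,PM3,PM5,PP1,PP2,PP3,PS3	pathogenic	0	0	classic	39/39
23	1612	cPKU	F	2023	unknown	NC_000012.12(NM_000277.3):c.165del	367	0.51	PVS1,PM2,PM3	pathogenic	0	0	classic	39/39
24	960	mPKU	M	1999	none	NC_000012.12(NM_000277.3):c.533A > G	67	0.36	PM1,PM2,PM3,PM5,PP2,PP3,PS3	pathogenic	7.5	7.5	mild_HPA	1/3
25	2460	cPKU	F	2001	third_degree_cousin	NC_000012.12(NM_000277.3):c.1066-11G > A	860	0.76	PM2,PM3,PS3	pathogenic	0	0	classic	673/681
26	1380	cPKU	F	1995	none	NC_000012.12(NM_000277.3):c.47_48del	53	0.28	PVS1,PM2,PM3,PS3	pathogenic	NA	NA	NA	NA
26	1380	cPKU	F	1995	none	NC_000012.12(NM_000277.3):c.727C > T	212	0.38	PVS1,PM2,PM3,PS3	pathogenic	NA	NA	NA	NA
27	870	mPKU	F	1999	third_degree_cousin	NC_000012.12(NM_000277.3):c.143 T > C	109	0.34	PM1,PM2,PM3,PP1,PP2,PP3,PS3	pathogenic	2	2	mild	30/49
27	870	mPKU	F	1999	third_degree_cousin	NC_000012.12(NM_000277.3):c.1066-11G > A	1051	0.31	PM2,PM3,PS3	pathogenic	0	2	mild	30/49
28	3540	cPKU	F	1997	none	NC_000012.12(NM_000277.3):c.842C > T	245	0.89	PM2,PM3,PM5,PP2,PP3,PS3	pathogenic	0	0	classic	207/208
29	806	mPKU	M	2004	second_degree_cousin	NC_000012.12(NM_000277.3):c.782G > A	259	0.58	PM1,PM2,PM3,PM5,PP2,PP3,PS3	pathogenic	1.5	1.5	classic	184/381
30	1266	cPKU	M	1997	none	NC_000012.12(NM_000277.3):c.1066-11G > A	2082	0.29	PM2,PM3,PS3	pathogenic	NA	NA	NA	NA
30	1266	cPKU	M	1997	none	NC_000012.12(NM_000277.3):c.169-13 T > G	3626	0.40	PM2,PM3	likely_pathogenic	NA	NA	NA	NA
31	666	mPKU	F	1997	none	NC_000012.12(NM_000277.3):c.143 T > C	388	0.63	PM1,PM2,PM3,PP1,PP2,PP3,PS3	pathogenic	2	2	classic	19/49
32	2130	cPKU	F	1998	none	NC_000012.12(NM_000277.3):c.1066-11G > A	359	0.43	PM2,PM3,PS3	pathogenic	0	1.5	classic	93/123
32	2130	cPKU	F	1998	none	NC_000012.12(NM_000277.3):c.782G > A	122	0.18	PM1,PM2,PM3,PM5,PP2,PP3,PS3	pathogenic	1.5	1.5	classic	93/123
33	guthrie_gt_8mgdl	cPKU	M	1997	none	NC_000012.12(NM_000277.3):c.1066-11G > A	1158	0.31	PM2,PM3,PS3	pathogenic	0	0	classic	673/681
34	1800	cPKU	M	2000	first_degree_cousin	NC_000012.12(NM_000277.3):c.353-1G > A	383	0.81	PVS1,PM2,PP5	pathogenic	0	0	classic	2/2
35	2310	cPKU	M	1998	first_degree_cousin	NC_000012.12(NM_000277.3):c.754C > T	144	0.69	PM1,PM2,PM3,PM5,PP1,PP2,PP3,PS3	pathogenic	0	0	classic	126/128
36	not_determined	mPKU	F	1997	yes_unknown_degree	NC_000012.12(NM_000277.3):c.1169A > G	413	0.27	PM1,PM2,PM3,PP2,PP3,PS3	pathogenic	6.8	6.8	mild_HPA	13/13
36	not_determined	mPKU	F	1997	yes_unknown_degree	NC_000012.12(NM_000277.3):c.1066-11G > A	442	0.28	PM2,PM3,PS3	pathogenic	0	6.8	mild_HPA	13/13
37	1362	mPKU	M	2001	second_degree_cousin	NC_000012.12(NM_000277.3):c.898G > T	439	0.67	PM1,PM2,PM3,PM5,PP2,PP3,PS3	pathogenic	9.7	9.7	mild_HPA	25/25
38	1800	cPKU	F	2000	first_degree_cousin	NC_000012.12(NM_000277.3):c.1087_1088del	1920	0.81	PVS1,PM2	likely_pathogenic	0	0	classic	60/61
39	2460	cPKU	M	2001	none	NC_000012.12(NM_000277.3):c.1068C > G	656	0.40	PVS1,PM2,PM3,PS3	pathogenic	NA	NA	NA	NA
39	2460	cPKU	M	2001	none	NC_000012.12(NM_000277.3):c.168G > T	108	0.46	PM2,PM3,PP2,PP3	pathogenic	NA	NA	NA	NA
40	guthrie_gt_8mgdl	cPKU	F	1989	none	NC_000012.12(NM_000277.3):c.1066-11G > A	921	0.33	PM2,PM3,PS3	pathogenic	NA	NA	NA	NA
40	guthrie_gt_8mgdl	cPKU	F	1989	none	NC_000012.12(NM_000277.3):c.724C > T	168	0.35	PM1,PM2,PM3,PP2,PP3	pathogenic	NA	NA	NA	NA
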