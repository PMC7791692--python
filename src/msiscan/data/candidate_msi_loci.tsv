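scaffold	position	motif	repeat_count	score_10mM	score_30mM	score_control
NW_020822370.1	34498325	GA	31	85.71	94.44	83.33
NW_020822370.1	29116483	AG	22	14.29	62.5	0
NW_020822370.1	8110802	GT	33	14.29	20	7.14
NW_020822373.1	4520712	TC	27	10.34	12.4	4.59
NW_020822375.1	17984519	GT	23	90	100	77.78
NW_020822375.1	24391224	CA	8	41.67	70	0
NW_020822376.1	2957094	CA	7	13.04	21.05	8.33
NW_020822382.1	3087333	CCTC	5	14.29	21.43	0
NW_020822403.1	19387296	AC	25	28.57	50	4.76
NW_020822403.1	15933029	AC	26	25	46.15	0
NW_020822406.1	3701096	GT	23	14.29	42.86	9.09
NW_020822407.1	7711795	AAAC	6	16.67	26.67	0
NW_020822409.1	5651224	AAT	12	14.29	44.44	0
NW_020822410.1	13888699	GT	28	83.33	90.32	63.64
NW_020822410.1	10858329	AC	19	94.12	96.15	75
NW_020822412.1	3775426	TG	26	21.43	28.57	0
NW_020822415.1	36220614	TC	31	91.67	92.31	57.14
NW_020822415.1	16052939	ACA	5	19.23	23.33	5.26
NW_020822421.1	5779917	TC	29	91.3	100	80
NW_020822426.1	5559446	GA	31	93.75	100	90.91
NW_020822426.1	3827444	TCT	30	71.43	72.73	55.56
NW_020822426.1	1539468	GT	22	27.27	28.57	0
NW_020822428.1	1367872	AC	26	93.75	100	85.71
NW_020822428.1	8085398	TCCT	11	16.67	27.27	0
NW_020822434.1	512274	GT	28	18.18	44.44	0
NW_020822436.1	3837117	AC	16	90.32	93.33	38
NW_020822439.1	68421902	AC	29	91.67	100	83.33
NW_020822439.1	47065858	TC	35	84.62	94.74	80
NW_020822439.1	62174741	GT	23	22.22	35.48	11.11
NW_020822439.1	14184660	AAAC	7	12	50	0
NW_020822439.1	66094811	AC	24	25	28.57	0
NW_020822439.1	16584719	GT	8	20	36.36	7.14
NW_020822439.1	2390672	TG	62	12.5	33.33	0
NW_020822439.1	243530	CA	25	25	50	0
NW_020822439.1	17884454	AGAT	11	13.33	20	7.14
NW_020822440.1	3560698	GA	28	88.89	90	83.33
NW_020822443.1	2115154	AC	27	27.27	43.75	9.09
NW_020822446.1	382267	CA	32	66.67	75	33
NW_020822450.1	9390312	AC	22	16.67	44.44	11.11
NW_020822452.1	9210374	CT	31	90	93.33	81.82
NW_020822458.1	15628677	AG	27	91.67	100	73.33
NW_020822461.1	21799265	TCTT	16	16.67	25	0
NW_020822464.1	1598541	AC	26	84.62	100	83.33
NW_020822464.1	6242934	TG	26	27.78	36	0
NW_020822465.1	1645147	TG	9	39.29	54.55	5.88
NW_020822468.1	15157395	GT	35	87.5	100	66.67
NW_020822469.1	3552281	GATG	8	31.25	54.55	0
NW_020822484.1	1703831	TG	7	95.65	100	77.27
NW_020822486.1	16687223	GT	23	21.43	22.22	0
NW_020822487.1	21884245	CT	34	89.66	96.43	80
NW_020822487.1	17786455	TC	30	91.67	100	87.5
NW_020822487.1	25648949	AC	15	25	37.5	10
NW_020822487.1	8954697	CA	29	10	18.18	0
NW_020822488.1	1550207	TG	26	85.71	100	75
NW_020822499.1	2670448	TG	31	95.65	100	84
NW_020822499.1	21810339	CT	20	35.71	56.25	0
NW_020822499.1	16894388	TTA	5	11.9	13.73	6.67
NW_020822499.1	10821740	TTGT	8	14.29	38.46	7.14
NW_020822501.1	11357080	GT	29	91.67	100	85.71
NW_020822501.1	14044688	TTG	7	14.29	24.32	3.33
NW_020822501.1	14071142	TTA	12	20	28.57	5.56
NW_020822501.1	17408028	TG	30	55.56	57.14	7.14
NW_020822503.1	10248411	CTTT	14	22.22	25	0
NW_020822503.1	4513778	GT	14	10.53	20	0
NW_020822503.1	17353421	GT	6	22.22	25	9.09
NW_020822504.1	9433369	TC	30	95	100	88.89
NW_020822504.1	13319850	TGTA	5	12.5	15.56	5.88
NW_020822505.1	16324767	CA	24	93.75	100	77.78
NW_020822505.1	16510213	AC	30	85.71	87.5	77.78
NW_020822505.1	10642584	TG	27	27.27	37.5	0
NW_020822508.1	1001369	AC	22	90.91	100	71.43
NW_020822508.1	2728629	TATC	10	16.67	27.78	0
NW_020822508.1	15865728	GAAG	13	7.69	31.25	0
NW_020822508.1	15865731	GAAG	13	7.14	26.32	0
NW_020822511.1	9568885	TG	29	92.31	100	83.33
NW_020822512.1	6724926	TG	30	87.5	93.33	85.71
NW_020822519.1	6274345	AC	25	91.67	100	84.62
NW_020822519.1	11516391	AG	36	15.79	37.5	0
NW_020822520.1	2511201	AC	24	20	25	0
NW_020822526.1	18794354	AC	26	91.67	100	83.33
NW_020822526.1	25646840	CA	7	90	100	77.78
NW_020822526.1	24206438	GT	30	87.5	90	70
NW_020822526.1	16873752	AG	32	83.33	100	69.23
NW_020822526.1	17494091	AC	16	17.65	57.14	0
NW_020822526.1	4205760	ATGT	11	16.67	37.5	0
NW_020822529.1	28253360	TG	23	91.67	100	86.67
NW_020822529.1	16865510	TC	27	42.86	54.55	0
NW_020822530.1	10618047	TG	22	18.18	28.57	0
NW_020822531.1	6287546	AC	27	90.91	93.75	81.82
NW_020822531.1	1037419	GT	44	45.45	50	12.5
NW_020822544.1	4160116	AAC	5	22.73	60	0
NW_020822567.1	4418183	TG	29	91.67	100	80
NW_020822567.1	6942408	AC	24	25	35.29	0
NW_020822567.1	3062112	CA	7	17.39	29.41	3.85
NW_020822567.1	1362729	GA	24	15.38	25	0
NW_020822570.1	21823495	TG	28	14.29	44.44	0
NW_020822591.1	7123790	TATT	6	94.44	100	80
NW_020822591.1	7780615	TAAA	8	33.33	37.5	0
NW_020822591.1	14941	GA	34	9.09	25	0
NW_020822591.1	8820175	TTAT	11	9.52	27.27	0
NW_020822592.1	4061125	AC	31	42.86	44.44	0
NW_020822595.1	5415636	CAAA	6	37.93	38.46	7.69
NW_020822597.1	5771854	TG	31	88.24	94.44	75
NW_020822601.1	72176322	CA	8	91.18	100	85.71
NW_020822601.1	61385941	AC	19	21.43	22.73	0
NW_020822602.1	6751043	TC	30	91.67	96.55	83.33
NW_020822602.1	9765422	AATA	7	15.38	15.79	0
NW_020822603.1	9112470	AC	25	92.31	100	66.67
NW_020822604.1	8845685	GT	6	10	37.5	0
NW_020822610.1	821820	AC	27	31.25	41.18	10
NW_020822614.1	8982333	ATAG	16	13.64	13.79	0
NW_020822629.1	5127703	AG	28	12.5	20	0
NW_020822629.1	6170860	CA	22	12.5	33.33	0
NW_020822634.1	2791562	TC	33	95.24	100	62.5
NW_020822638.1	3030009	AC	21	92.31	100	58.33
NW_020822698.1	6755673	GT	27	90	100	80
NW_020822698.1	121373	TG	30	28.57	37.5	0
NW_020822785.1	9557	CA	14	14.29	75	0
NW_020822967.1	23702	CA	17	15.38	33.33	9.09
NW_020823044.1	10660	TTG	6	15.29	15.45	2.53
NW_020823531.1	97528	AG	22	11.76	15.22	5.41
NW_020823768.1	45602	TC	26	93.75	95.83	78.95
NW_020824031.1	35819	AC	23	20	25	0
NW_020824065.1	30045	AG	6	12	14.29	4.65
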