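family	family_count	family_pct	subfamily	subfamily_count	subfamily_pct
CYP1004	34	1.29	A	17	0.64
CYP1004	34	1.29	B	17	0.64
CYP1005	127	4.81	A	127	4.79
CYP1037	2	0.08	B	2	0.08
CYP1051	60	2.27	A	60	2.26
CYP1056	2	0.08	B	2	0.08
CYP105	600	22.70	AB	124	4.67
CYP105	600	22.70	AH	4	0.15
CYP105	600	22.70	B	1	0.04
CYP105	600	22.70	BL	78	2.94
CYP105	600	22.70	BN	1	0.04
CYP105	600	22.70	CH	44	1.66
CYP105	600	22.70	CN	62	2.34
CYP105	600	22.70	CP	62	2.34
CYP105	600	22.70	CT	41	1.55
CYP105	600	22.70	EJ	3	0.11
CYP105	600	22.70	G	62	2.34
CYP105	600	22.70	H	3	0.11
CYP105	600	22.70	J	52	1.96
CYP105	600	22.70	W	63	2.37
CYP107	551	20.85	AW	65	2.45
CYP107	551	20.85	AX	75	2.83
CYP107	551	20.85	AY	116	4.37
CYP107	551	20.85	CL	3	0.11
CYP107	551	20.85	CT	6	0.23
CYP107	551	20.85	E	38	1.43
CYP107	551	20.85	EP	2	0.08
CYP107	551	20.85	EU	44	1.66
CYP107	551	20.85	FH	25	0.94
CYP107	551	20.85	FJ	20	0.75
CYP107	551	20.85	FS	61	2.30
CYP107	551	20.85	GU	1	0.04
CYP107	551	20.85	HF	2	0.08
CYP107	551	20.85	LA	6	0.23
CYP107	551	20.85	N	2	0.08
CYP107	551	20.85	NE	2	0.08
CYP107	551	20.85	NF	2	0.08
CYP107	551	20.85	NG	4	0.15
CYP107	551	20.85	NH	8	0.30
CYP107	551	20.85	Q	63	2.37
CYP107	551	20.85	Z	6	0.23
CYP1114	1	0.04	C	1	0.04
CYP113	24	0.91	B	6	0.23
CYP113	24	0.91	D	1	0.04
CYP113	24	0.91	E	10	0.38
CYP113	24	0.91	R	2	0.08
CYP113	24	0.91	S	2	0.08
CYP113	24	0.91	T	1	0.04
CYP113	24	0.91	X	2	0.08
CYP1197	1	0.04	A	1	0.04
CYP1198	43	1.63	B	43	1.62
CYP1207	4	0.15	A	4	0.15
CYP1223	6	0.23	D	2	0.08
CYP1223	6	0.23	A	4	0.15
CYP1226	2	0.08	A	2	0.08
CYP124	15	0.57	M	15	0.57
CYP125	164	6.21	A	128	4.82
CYP125	164	6.21	G	36	1.36
CYP1269	2	0.08	A	2	0.08
CYP1278	11	0.42	A	5	0.19
CYP1278	11	0.42	B	6	0.23
CYP1437	1	0.04	C	1	0.04
CYP146	1	0.04	A	1	0.04
CYP1522	1	0.04	A	1	0.04
CYP154	155	5.86	AJ	4	0.15
CYP154	155	5.86	J	1	0.04
CYP154	155	5.86	M	150	5.65
CYP1611	1	0.04	B	1	0.04
CYP161	28	1.06	N	23	0.87
CYP161	28	1.06	T	5	0.19
CYP162	39	1.48	A	11	0.41
CYP162	39	1.48	B	2	0.08
CYP162	39	1.48	G	2	0.08
CYP162	39	1.48	H	1	0.04
CYP162	39	1.48	J	1	0.04
CYP162	39	1.48	K	1	0.04
CYP162	39	1.48	L	1	0.04
CYP162	39	1.48	M	1	0.04
CYP162	39	1.48	N	1	0.04
CYP162	39	1.48	P	18	0.68
CYP163	39	1.48	A	2	0.08
CYP163	39	1.48	B	37	1.39
CYP164	4	0.15	C	4	0.15
CYP166	62	2.35	A	62	2.34
CYP173	1	0.04	K	1	0.04
CYP1902	2	0.08	A	2	0.08
CYP2054	22	0.83	A	22	0.83
CYP205	1	0.04	A	1	0.04
CYP208	126	4.77	A	126	4.75
CYP2091	1	0.04	A	1	0.04
CYP2098	2	0.08	A	2	0.08
CYP211	225	8.51	B	124	4.67
CYP211	225	8.51	C	101	3.81
CYP2296	1	0.04	A	1	0.04
CYP244	107	4.05	A	107	4.03
CYP245	83	3.14	A	83	3.13
CYP247	21	0.79	A	21	0.79
CYP248	63	2.38	A	63	2.37
CYP2611	1	0.04	B	1	0.04
CYP283	1	0.04	A	1	0.04
CYP285	4	0.15	A	2	0.08
CYP285	4	0.15	D	2	0.08
CYP294A4	2	0.08	A	2	0.08
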