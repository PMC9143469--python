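species	n_p450	n_fragments	n_families	n_subfamilies
Salinispora arenicola CNH996	26	6	14	25
Salinispora arenicola CNH996B	27	0	14	25
Salinispora arenicola CNY280	35	0	18	32
Salinispora arenicola CNH877	34	0	15	30
Salinispora arenicola CNS848	32	0	16	29
Salinispora arenicola CNT798	31	0	14	27
Salinispora arenicola CNH643	31	1	14	28
Salinispora arenicola CNS-991	31	0	15	28
Salinispora arenicola CNT799	31	0	14	28
Salinispora arenicola CNY679	31	1	14	27
Salinispora arenicola CNT850	31	0	13	27
Salinispora arenicola CNT800	31	0	14	28
Salinispora arenicola CNY011	31	0	14	26
Salinispora arenicola CNY230	30	0	17	30
Salinispora arenicola CNH713	30	0	14	27
Salinispora arenicola CNH905	31	1	14	28
Salinispora arenicola CNT857	30	0	14	28
Salinispora arenicola CNY281	29	1	17	29
Salinispora arenicola CNH941	29	0	14	26
Salinispora arenicola CNB527	29	4	15	27
Salinispora arenicola CNT859	29	0	13	26
Salinispora arenicola CNT005	28	0	16	28
Salinispora arenicola CNH964	28	1	14	24
Salinispora arenicola CNP193	28	0	14	26
Salinispora arenicola CNP105	28	2	14	25
Salinispora arenicola CNH646	28	0	14	26
Salinispora arenicola CNR425	28	0	15	28
Salinispora arenicola CNS-205	28	1	15	28
Salinispora arenicola ATCC BAA-917	27	13	11	21
Salinispora arenicola CNY685	26	6	14	26
Salinispora arenicola CNS325	26	0	13	26
Salinispora arenicola CNS744	26	0	13	26
Salinispora arenicola CNY694	26	6	13	26
Salinispora arenicola CNY260	26	0	14	26
Salinispora arenicola CNT-088	26	1	13	24
Salinispora arenicola CNB458	26	4	13	26
Salinispora arenicola CNS296	25	1	14	25
Salinispora arenicola CNY231	25	0	14	26
Salinispora arenicola CNY282	25	0	13	25
Salinispora arenicola CNS299	25	1	14	25
Salinispora arenicola CNQ748	25	0	13	25
Salinispora arenicola CNY244	25	0	13	25
Salinispora arenicola CNS820	25	0	13	25
Salinispora arenicola CNS673	25	0	13	25
Salinispora arenicola CNY237	24	0	12	24
Salinispora arenicola CNS342	24	1	13	24
Salinispora arenicola CNH718	24	1	13	24
Salinispora arenicola CNX891	24	3	15	24
Salinispora arenicola CNY256	24	0	13	25
Salinispora arenicola CNS243	24	1	13	24
Salinispora arenicola CNY234	24	1	13	24
Salinispora arenicola CNY690	24	4	13	24
Salinispora arenicola CNQ884	23	1	13	25
Salinispora arenicola CNR107	22	0	12	22
Salinispora arenicola CNR921	22	0	12	22
Salinispora arenicola CNH962	22	1	12	22
Salinispora arenicola CNX481	22	2	12	22
Salinispora arenicola CNH963	22	1	12	22
Salinispora arenicola CNX814	22	1	12	21
Salinispora arenicola CNY486	22	1	13	24
Salinispora arenicola CNX508	21	1	12	21
Salinispora arenicola CNX482	21	1	12	21
Salinispora pacifica CNS996	21	1	15	21
Salinispora pacifica CNS237	20	1	12	19
Salinispora pacifica CNY646	20	1	13	19
Salinispora tropica CNT261	20	2	10	18
Salinispora pacifica DSM 45548	19	0	7	10
Salinispora pacifica CNT045	19	1	13	19
Salinispora pacifica CNT124	19	0	13	19
Salinispora pacifica DSM 45543	19	0	12	18
Salinispora tropica CNB536	19	0	11	19
Salinispora tropica CNH898	18	1	11	20
Salinispora pacifica CNT403	18	1	12	17
Salinispora pacifica CNS860	18	2	11	16
Salinispora pacifica CNS863	18	2	12	17
Salinispora tropica CNY012	18	2	10	18
Salinispora pacifica CNT584	17	0	11	17
Salinispora pacifica DSM 45549	17	1	11	16
Salinispora pacifica CNR114	17	1	13	17
Salinispora tropica CNR699	17	2	10	16
Salinispora pacifica CNT854	18	0	13	18
Salinispora pacifica CNT150	17	1	11	16
Salinispora pacifica CNT131	17	1	11	15
Salinispora pacifica DSM 45544	16	0	11	16
Salinispora pacifica CNT003	16	1	10	15
Salinispora tropica CNY681	16	1	10	16
Salinispora tropica CNS197	16	1	10	16
Salinispora tropica CNY678	16	1	10	16
Salinispora tropica CNT250	16	1	10	16
Salinispora tropica CNB-440	16	1	10	16
Salinispora tropica CNS416	15	0	9	15
Salinispora pacifica CNT001	15	1	11	15
Salinispora pacifica CNY498	15	1	11	15
Salinispora pacifica CNR909	15	1	10	15
Salinispora tropica CNB476	15	1	9	15
Salinispora pacifica CNR894	15	0	11	15
Salinispora pacifica CNY363	15	0	11	15
Salinispora pacifica CNS055	15	0	9	15
Salinispora pacifica CNT603	15	1	11	15
Salinispora pacifica CNT138	14	0	10	14
Salinispora pacifica DSM 45547	14	1	10	14
Salinispora pacifica CNH732	14	1	10	14
Salinispora pacifica CNY703	14	0	9	13
Salinispora pacifica CNQ768	14	1	10	14
Salinispora pacifica CNY673	14	0	10	14
Salinispora pacifica CNT855	14	0	9	14
Salinispora pacifica CNY239	14	1	10	14
Salinispora pacifica CNR942	14	1	10	14
Salinispora pacifica DSM 45546	14	1	10	14
Salinispora pacifica CNT609	14	1	10	14
Salinispora pacifica CNY331	14	0	10	14
Salinispora tropica CNR416	14	0	9	14
Salinispora pacifica CNY330	13	0	9	13
Salinispora pacifica CNT851	13	1	9	13
Salinispora pacifica CNT796	13	1	9	13
Salinispora pacifica CNS103	13	0	9	13
Salinispora pacifica CNY202	13	1	9	13
Salinispora pacifica CNT133A	13	0	9	13
Salinispora arenicola CNY666	13	5	8	13
Salinispora pacifica CNT029	13	1	9	13
Salinispora pacifica CNT084	13	0	9	13
Salinispora pacifica CNR510	13	0	9	13
Salinispora pacifica CNT569	12	1	9	13
Salinispora pacifica CNT-133	11	11	7	9
Salinispora pacifica CNS801	10	0	7	10
Salinispora pacifica CNT148	10	0	7	10
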