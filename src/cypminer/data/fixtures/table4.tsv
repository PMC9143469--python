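bgc_type	bgc_type_count	variety_count	p450_list	p450_count
Bacteriocin	47	46	CYP107AW	46
Bacteriocin	47	1	CYP283A	1
betalactone	2	1	CYP162A6,CYP107HF1	2
betalactone	2	1	CYP113S1	1
butyrolactone	1	1	CYP105CT1,CYP154M5	2
Indole	54	51	CYP244A,CYP245A	102
Indole	54	3	CYP244A	3
ladderane	18	4	CYP154M15,CYP125G6,CYP107FS2,CYP105CN1,CYP105CP2	20
ladderane	18	8	CYP107AX-fragment	8
ladderane	18	6	CYP107AX	6
lanthipeptide	2	1	CYP1223A5	1
lanthipeptide	2	1	CYP105CP2,CYP105CN1,CYP107FS2,CYP248A2,CYP105W2	5
LAP	1	1	CYP154AJ2	1
lipolanthine	2	2	CYP1223A5	2
NRPS	205	1	CYP1004B1,CYP1004A1	2
NRPS	205	8	CYP1004B,CYP1004A,CYP125G	24
NRPS	205	1	CYP105CH2-fragment,CYP105CH1-fragment	2
NRPS	205	1	CYP105CN1	1
NRPS	205	1	CYP105CN1,CYP105CP2	2
NRPS	205	1	CYP105CN1,CYP107FS2,CYP125G6,CYP154M15	4
NRPS	205	1	CYP105CN1,CYP107FS2,CYP247A7	3
NRPS	205	1	CYP105CP2	1
NRPS	205	7	CYP105CP2,CYP105CN1,CYP107FS2	21
NRPS	205	10	CYP105CP2,CYP105CN1,CYP107FS2,CYP125G6,CYP154M15	50
NRPS	205	2	CYP105CP2,CYP105CN1,CYP107FS2,CYP248A2	8
NRPS	205	1	CYP105CP2,CYP105CN1,CYP107FS2,CYP248A2,CYP105W2	5
NRPS	205	3	CYP105W	3
NRPS	205	38	CYP107AY	38
NRPS	205	1	CYP107AY14,CYP244A-fragment2	2
NRPS	205	6	CYP107AY2,CYP105CT1,CYP154M5	18
NRPS	205	1	CYP107AY2,CYP163B16	2
NRPS	205	1	CYP107AY7,CYP244A5,CYP245A11	3
NRPS	205	1	CYP107AY9,CYP162B3	2
NRPS	205	1	CYP107AY9,CYP244A10	2
NRPS	205	2	CYP107CL2,CYP1056B2	4
NRPS	205	5	CYP107CT3	5
NRPS	205	1	CYP107CT3,CYP107AY7	2
NRPS	205	1	CYP107FS2	1
NRPS	205	6	CYP107FS2,CYP105CN1,CYP105CP2	18
NRPS	205	2	CYP107NH1,CYP247A8,CYP107Z27	6
NRPS	205	1	CYP107Z27,CYP247A8,CYP107NH1	3
NRPS	205	1	CYP113D13,CYP163B22	2
NRPS	205	1	CYP1196A2	1
NRPS	205	1	CYP1198B1	1
NRPS	205	1	CYP1198B1,CYP107AY2	2
NRPS	205	2	CYP1207A12	2
NRPS	205	1	CYP125G1,CYP1004A1,CYP1004B1	3
NRPS	205	1	CYP125G6,CYP154M15	2
NRPS	205	4	CYP1278A4	4
NRPS	205	1	CYP1437C1	1
NRPS	205	1	CYP154AJ3	1
NRPS	205	1	CYP154J2,CYP244A5,CYP245A11	3
NRPS	205	5	CYP154M1,CYP208A4	10
NRPS	205	6	CYP154M	6
NRPS	205	3	CYP154M,CYP208A	6
NRPS	205	1	CYP154M16,CYP211C6	2
NRPS	205	1	CYP154M21,CYP154M13	2
NRPS	205	1	CYP154M21,CYP154M13,CYP105W2,CYP248A2	4
NRPS	205	3	CYP154M21,CYP154M13,CYP105W2,CYP248A2,CYP154M20	15
NRPS	205	1	CYP154M21,CYP154M13,CYP105W2,CYP248A2,CYP154M20,CYP162P1	6
NRPS	205	12	CYP162	12
NRPS	205	1	CYP163A10,CYP162K1	2
NRPS	205	15	CYP163B	15
NRPS	205	3	CYP164C2	3
NRPS	205	5	CYP208A21,CYP154M16	10
NRPS	205	2	CYP208A4,CYP154M1	4
NRPS	205	8	CYP244A,CYP107AY	16
NRPS	205	5	CYP244A5,CYP245A11	10
NRPS	205	2	CYP244A,CYP107AY	4
NRPS	205	2	CYP244A	2
NRPS	205	1	CYP245A11	1
NRPS	205	3	CYP247A	3
NRPS	205	1	CYP247A8,CYP107NH1	2
NRPS	205	1	CYP247A8,CYP107Z27	2
NRPS	205	1	CYP248A2	1
NRPS	205	1	CYP248A2,CYP105W2	2
NRPS	205	1	CYP285D2	1
NRPS-like	30	5	CYP107EU	5
NRPS-like	30	1	CYP107EU1,CYP1198B1,CYP105CH1	3
NRPS-like	30	1	CYP107FH3,CYP161N4,CYP107AY9	3
NRPS-like	30	7	CYP107FH3,CYP2054A3,CYP161N4	21
NRPS-like	30	2	CYP161N4,CYP2054A3,CYP107FH3	6
NRPS-like	30	6	CYP162A8	6
NRPS-like	30	6	CYP166A4	6
NRPS-like	30	1	CYP166A4,CYP107Q4,CYP105G5	3
NRPS-like	30	1	CYP285A9-fragment,CYP285A9-fragment	2
oligosaccharide	35	1	CYP105CP2	1
oligosaccharide	35	1	CYP105W2,CYP107FS2,CYP105CN1,CYP105CP2	4
oligosaccharide	35	1	CYP105W2,CYP107NH1	2
oligosaccharide	35	1	CYP105W2,CYP154M20,CYP154M13,CYP154M21,CYP248A2	5
oligosaccharide	35	5	CYP105W2,CYP248A2	10
oligosaccharide	35	1	CYP105W2,CYP248A2,CYP107FS2	3
oligosaccharide	35	9	CYP105W2/3,CYP248A2,CYP107FS2,CYP105CN1,CYP105CP2	45
oligosaccharide	35	1	CYP1269A2	1
oligosaccharide	35	8	CYP154M20,CYP248A2,CYP105W2,CYP154M13,CYP154M21	40
oligosaccharide	35	1	CYP2091A1	1
oligosaccharide	35	3	CYP248A2	3
oligosaccharide	35	3	CYP248A2,CYP105W2/3	6
other	4	2	CYP247A7	2
other	4	2	CYP105AH4	2
other	4	1	CYP1004A3,CYP1004B4,CYP113E2,CYP163B18	4
T1PKS	223	1	CYP105AH4	1
T1PKS	223	1	CYP105BN4	1
T1PKS	223	17	CYP105CH1/2	17
T1PKS	223	1	CYP105CN1	1
T1PKS	223	4	CYP105G5	4
T1PKS	223	16	CYP105G5,CYP107Q4	32
T1PKS	223	2	CYP105H11	2
T1PKS	223	1	CYP107AY13	1
T1PKS	223	24	CYP107E	24
T1PKS	223	1	CYP107E3,CYP125G1,CYP1004A1,CYP1004B1	4
T1PKS	223	8	CYP107EU1	8
T1PKS	223	2	CYP107FH4	2
T1PKS	223	1	CYP107NE1	1
T1PKS	223	3	CYP107Q4	3
T1PKS	223	17	CYP107Q4,CYP105G5	34
T1PKS	223	6	CYP113E1/2	6
T1PKS	223	1	CYP113E2,CYP107EP2	2
T1PKS	223	2	CYP1198B2	2
T1PKS	223	1	CYP125G1	1
T1PKS	223	1	CYP1278B-fragment2	1
T1PKS	223	5	CYP154M5,CYP105CT1	10
T1PKS	223	1	CYP154M5,CYP105CT1,CYP105G5,CYP105CP2	4
T1PKS	223	1	CYP154M5,CYP105CT1,CYP107AY2-fragment	3
T1PKS	223	1	CYP154M5,CYP105CT2	2
T1PKS	223	1	CYP1611B1,CYP2098A1	2
T1PKS	223	29	CYP166A4	29
T1PKS	223	1	CYP166A4,CYP107Q4,CYP105G5	3
T1PKS	223	70	CYP208A	70
T1PKS	223	1	CYP208A28,CYP154M18	2
T1PKS	223	1	CYP211C5	1
T1PKS	223	2	CYP294A4	2
T2PKS	76	2	CYP107NG1	2
T2PKS	76	1	CYP107NH1	1
T2PKS	76	1	CYP125G4	1
T2PKS	76	1	CYP161T1	1
T2PKS	76	69	CYP211C	69
T2PKS	76	1	CYP2296A2,CYP166A4,CYP173K1	3
T2PKS	76	1	CYP244A5,CYP211C6	2
T3PKS	8	7	CYP161N4,CYP2054A3,CYP107FH3	21
T3PKS	8	1	CYP107FH3	1
Terpene	61	39	CYP1051A	39
Terpene	61	2	CYP105CT1	2
Terpene	61	7	CYP105CT1,CYP154M5	14
Terpene	61	6	CYP107AY	6
Terpene	61	4	CYP107AY9,CYP244A10	8
Terpene	61	1	CYP107E37	1
Terpene	61	1	CYP154AJ2	1
Terpene	61	1	CYP154M5	1
transAT-PKS	1	1	CYP113 × 1	1
transAT-PKS-like	8	8	CYP163B	8
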