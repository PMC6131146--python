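case	sample_id	lesion	lesion_type	months	diagnosis	group	esv	gcs	gband
1	1A	PT	PT	0	MLS	MLS	7	4	5
1	1B	LR2	LR	22	MLS	MLS	9	4	4
2	2A	PT	PT	0	MLS	MLS	18	0	1
2	2B	Met1	Met	30	MLS	MLS	20	0	1
2	2C	Met2	Met	92	MLS	MLS	ND	ND	2
2	2D	Met3	Met	98	MLS	MLS	ND	ND	2
3	3A	PT	PT	0	MLS	MLS	12	0	1
3	3B	Met1	Met	19	MLS	MLS	23	8	1
3	3C	Met2a	Met	28	MLS	MLS	ND	ND	1
3	3D	Met2b	Met	28	MLS	MLS	ND	ND	1
3	3E	Met3	Met	32	MLS	MLS	ND	ND	1
4	4A	PT	PT	0	MLS	MLS	165	2	5
4	4B	Met1	Met	19	MLS	MLS	11	3	5
4	4C	Met2a	Met	20	MLS	MLS	16	3	5
4	4D	Met2b	Met	20	MLS	MLS	14	3	5
4	4E	Met3	Met	74	MLS	MLS	24	4	5
5	5A	PT	PT	0	MLS	MLS	ND	0	1
5	5B	LR1	LR	104	MLS	MLS	ND	1	1
6	6A	PT	PT	0	MLS	MLS	ND	5	3
6	6B	LR1	LR	12	MLS	MLS	ND	0	1
7	7A	PT	PT	0	MLS	MLS	ND	1	1
7	7B	LR1	LR	25	MLS	MLS	ND	1	1
8	8A	PT	PT	0	MLS	MLS	ND	ND	4
8	8B	Met1	Met	48	MLS	MLS	ND	ND	4
9	9A	PT	PT	0	MLS	MLS	ND	ND	1
9	9B	Met1	Met	42	MLS	MLS	ND	ND	1
10	10A	PT	PT	0	WDLS	WDLS	5	38	8
10	10B	LR1	LR	197	WDLS	WDLS	1	35	3
10	10C	LR2	LR	306	WDLS	WDLS	8	37	2
11	11A	PT	PT	0	WDLS	WDLS	ND	ND	ND
11	11B	LR1	LR	84	WDLS	WDLS	4	35	1
11	11C	LR2	LR	124	WDLS	WDLS	7	22	>10
11	11D	LR3	LR	141	WDLS	WDLS	9	35	6
12	12A	PT	PT	0	WDLS	WDLS	6	38	4
12	12B	LR1	LR	124	WDLS	WDLS	4	51	>3
13	13A	PT	PT	0	WDLS	WDLS	11	27	11
13	13B	LR2	LR	215	WDLS	WDLS	7	23	4
14	14A	PT	PT	0	WDLS	WDLS	7	35	3
14	14B	LR1	LR	211	WDLS	WDLS	8	39	5
15	15A	PT	PT	0	MFS	CXS	32	91	NA
15	15B	LR1	LR	47	MFS	CXS	46	99	NA
15	15C	Met1	Met	114	MFS	CXS	68	84	NA
16	16A	PT	PT	0	MFS	CXS	ND	ND	NA
16	16B	LR1	LR	60	MFS	CXS	29	33	NA
16	16C	LR2	LR	100	MFS	CXS	31	22	NA
16	16D	LR6	LR	152	MFS	CXS	33	28	NA
17	17A	PT	PT	0	MFS	CXS	5	151	NA
17	17B	Met3	Met	77	MFS	CXS	19	114	NA
18	18A	PT	PT	0	MFS	CXS	15	27	NA
18	18B	LR2	LR	110	MFS	CXS	13	30	NA
19	19A	PT	PT	0	MFS	CXS	25	80	NA
19	19B	Met1	Met	86	MFS	CXS	27	141	NA
20	20A	PT	PT	0	Myoep	CXS	10	110	NA
20	20B	LR2	LR	294	Myoep	CXS	9	99	NA
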