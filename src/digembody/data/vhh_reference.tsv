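# IMGT-numbered camelid VHH framework reference used for numbering transfer.
# A synthetic consensus single-domain framework: framework identities follow
# the VHH consensus (conserved C23/C104, hallmark W41, interface residues
# S7 L12 Q14 Q44 P46 G47 K84 Q120 Q123 T125); CDR identities are placeholders
# with typical loop lengths.  Columns: imgt_position, region, amino_acid.
1	FR1	Q
2	FR1	V
3	FR1	Q
4	FR1	L
5	FR1	V
6	FR1	E
7	FR1	S
8	FR1	G
9	FR1	G
11	FR1	G
12	FR1	L
13	FR1	V
14	FR1	Q
15	FR1	P
16	FR1	G
17	FR1	G
18	FR1	S
19	FR1	L
20	FR1	R
21	FR1	L
22	FR1	S
23	FR1	C
24	FR1	A
25	FR1	A
26	FR1	S
27	CDR1	G
28	CDR1	R
29	CDR1	T
30	CDR1	F
35	CDR1	S
36	CDR1	S
37	CDR1	Y
38	CDR1	A
39	FR2	M
40	FR2	G
41	FR2	W
42	FR2	F
43	FR2	R
44	FR2	Q
45	FR2	A
46	FR2	P
47	FR2	G
48	FR2	K
49	FR2	Q
50	FR2	R
51	FR2	E
52	FR2	L
53	FR2	V
54	FR2	S
55	FR2	A
56	CDR2	I
57	CDR2	N
58	CDR2	S
59	CDR2	G
62	CDR2	G
63	CDR2	S
64	CDR2	S
65	CDR2	T
66	FR3	N
67	FR3	Y
68	FR3	A
69	FR3	D
70	FR3	S
71	FR3	V
72	FR3	K
73	FR3	G
74	FR3	R
75	FR3	F
76	FR3	T
77	FR3	I
78	FR3	S
79	FR3	R
80	FR3	D
81	FR3	N
82	FR3	A
83	FR3	K
84	FR3	K
85	FR3	T
86	FR3	V
87	FR3	Y
88	FR3	L
89	FR3	Q
90	FR3	M
91	FR3	N
92	FR3	S
93	FR3	L
94	FR3	K
95	FR3	P
96	FR3	E
97	FR3	D
98	FR3	T
99	FR3	A
100	FR3	V
101	FR3	I
102	FR3	Y
103	FR3	Y
104	FR3	C
105	CDR3	A
106	CDR3	A
107	CDR3	D
108	CDR3	S
109	CDR3	T
113	CDR3	G
114	CDR3	Y
115	CDR3	D
116	CDR3	Y
117	CDR3	E
118	FR4	W
119	FR4	G
120	FR4	Q
121	FR4	G
122	FR4	T
123	FR4	Q
124	FR4	V
125	FR4	T
126	FR4	V
127	FR4	S
128	FR4	S
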