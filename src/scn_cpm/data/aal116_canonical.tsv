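region_id	network
1	MOT
2	MOT
3	FP
4	FP
5	SC
6	SC
7	FP
8	FP
9	SC
10	SC
11	FP
12	FP
13	FP
14	FP
15	SC
16	SC
17	MOT
18	MOT
19	MOT
20	MOT
21	MF
22	MF
23	DMN
24	DMN
25	MF
26	MF
27	MF
28	MF
29	SC
30	SC
31	MF
32	MF
33	DMN
34	DMN
35	DMN
36	DMN
37	SC
38	SC
39	SC
40	SC
41	SC
42	SC
43	VIS
44	VIS
45	VA
46	VA
47	VIS
48	VIS
49	VIS
50	VIS
51	VA
52	VA
53	VA
54	VA
55	VA
56	VA
57	MOT
58	MOT
59	FP
60	FP
61	FP
62	FP
63	FP
64	FP
65	DMN
66	DMN
67	DMN
68	DMN
69	MOT
70	MOT
71	SC
72	SC
73	SC
74	SC
75	SC
76	SC
77	SC
78	SC
79	MOT
80	MOT
81	MOT
82	MOT
83	SC
84	SC
85	DMN
86	DMN
87	SC
88	SC
89	VA
90	VA
91	SC
92	SC
93	SC
94	SC
95	SC
96	SC
97	SC
98	SC
99	SC
100	SC
101	SC
102	SC
103	SC
104	SC
105	SC
106	SC
107	SC
108	SC
109	SC
110	SC
111	SC
112	SC
113	SC
114	SC
115	SC
116	SC
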