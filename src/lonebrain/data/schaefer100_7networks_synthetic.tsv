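index	name	hemisphere	network
0	7Networks_LH_Visual_1	left	Visual
1	7Networks_LH_Visual_2	left	Visual
2	7Networks_LH_Visual_3	left	Visual
3	7Networks_LH_Visual_4	left	Visual
4	7Networks_LH_Visual_5	left	Visual
5	7Networks_LH_Visual_6	left	Visual
6	7Networks_LH_Visual_7	left	Visual
7	7Networks_LH_SomMot_1	left	SomMot
8	7Networks_LH_SomMot_2	left	SomMot
9	7Networks_LH_SomMot_3	left	SomMot
10	7Networks_LH_SomMot_4	left	SomMot
11	7Networks_LH_SomMot_5	left	SomMot
12	7Networks_LH_SomMot_6	left	SomMot
13	7Networks_LH_SomMot_7	left	SomMot
14	7Networks_LH_SomMot_8	left	SomMot
15	7Networks_LH_DorsalAttn_1	left	DorsalAttn
16	7Networks_LH_DorsalAttn_2	left	DorsalAttn
17	7Networks_LH_DorsalAttn_3	left	DorsalAttn
18	7Networks_LH_DorsalAttn_4	left	DorsalAttn
19	7Networks_LH_DorsalAttn_5	left	DorsalAttn
20	7Networks_LH_DorsalAttn_6	left	DorsalAttn
21	7Networks_LH_DorsalAttn_7	left	DorsalAttn
22	7Networks_LH_Salience_1	left	Salience
23	7Networks_LH_Salience_2	left	Salience
24	7Networks_LH_Salience_3	left	Salience
25	7Networks_LH_Salience_4	left	Salience
26	7Networks_LH_Salience_5	left	Salience
27	7Networks_LH_Salience_6	left	Salience
28	7Networks_LH_Limbic_1	left	Limbic
29	7Networks_LH_Limbic_2	left	Limbic
30	7Networks_LH_Limbic_3	left	Limbic
31	7Networks_LH_Limbic_4	left	Limbic
32	7Networks_LH_Limbic_5	left	Limbic
33	7Networks_LH_Control_1	left	Control
34	7Networks_LH_Control_2	left	Control
35	7Networks_LH_Control_3	left	Control
36	7Networks_LH_Control_4	left	Control
37	7Networks_LH_Control_5	left	Control
38	7Networks_LH_Control_6	left	Control
39	7Networks_LH_Control_7	left	Control
40	7Networks_LH_Default_1	left	Default
41	7Networks_LH_Default_2	left	Default
42	7Networks_LH_Default_3	left	Default
43	7Networks_LH_Default_4	left	Default
44	7Networks_LH_Default_5	left	Default
45	7Networks_LH_Default_6	left	Default
46	7Networks_LH_Default_7	left	Default
47	7Networks_LH_Default_8	left	Default
48	7Networks_LH_Default_9	left	Default
49	7Networks_LH_Default_10	left	Default
50	7Networks_RH_Visual_1	right	Visual
51	7Networks_RH_Visual_2	right	Visual
52	7Networks_RH_Visual_3	right	Visual
53	7Networks_RH_Visual_4	right	Visual
54	7Networks_RH_Visual_5	right	Visual
55	7Networks_RH_Visual_6	right	Visual
56	7Networks_RH_Visual_7	right	Visual
57	7Networks_RH_SomMot_1	right	SomMot
58	7Networks_RH_SomMot_2	right	SomMot
59	7Networks_RH_SomMot_3	right	SomMot
60	7Networks_RH_SomMot_4	right	SomMot
61	7Networks_RH_SomMot_5	right	SomMot
62	7Networks_RH_SomMot_6	right	SomMot
63	7Networks_RH_SomMot_7	right	SomMot
64	7Networks_RH_SomMot_8	right	SomMot
65	7Networks_RH_DorsalAttn_1	right	DorsalAttn
66	7Networks_RH_DorsalAttn_2	right	DorsalAttn
67	7Networks_RH_DorsalAttn_3	right	DorsalAttn
68	7Networks_RH_DorsalAttn_4	right	DorsalAttn
69	7Networks_RH_DorsalAttn_5	right	DorsalAttn
70	7Networks_RH_DorsalAttn_6	right	DorsalAttn
71	7Networks_RH_DorsalAttn_7	right	DorsalAttn
72	7Networks_RH_Salience_1	right	Salience
73	7Networks_RH_Salience_2	right	Salience
74	7Networks_RH_Salience_3	right	Salience
75	7Networks_RH_Salience_4	right	Salience
76	7Networks_RH_Salience_5	right	Salience
77	7Networks_RH_Salience_6	right	Salience
78	7Networks_RH_Limbic_1	right	Limbic
79	7Networks_RH_Limbic_2	right	Limbic
80	7Networks_RH_Limbic_3	right	Limbic
81	7Networks_RH_Limbic_4	right	Limbic
82	7Networks_RH_Limbic_5	right	Limbic
83	7Networks_RH_Control_1	right	Control
84	7Networks_RH_Control_2	right	Control
85	7Networks_RH_Control_3	right	Control
86	7Networks_RH_Control_4	right	Control
87	7Networks_RH_Control_5	right	Control
88	7Networks_RH_Control_6	right	Control
89	7Networks_RH_Control_7	right	Control
90	7Networks_RH_Default_1	right	Default
91	7Networks_RH_Default_2	right	Default
92	7Networks_RH_Default_3	right	Default
93	7Networks_RH_Default_4	right	Default
94	7Networks_RH_Default_5	right	Default
95	7Networks_RH_Default_6	right	Default
96	7Networks_RH_Default_7	right	Default
97	7Networks_RH_Default_8	right	Default
98	7Networks_RH_Default_9	right	Default
99	7Networks_RH_Default_10	right	Default
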