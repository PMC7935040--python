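region_id	region_name
0	Precentral_L
1	Precentral_R
2	Frontal_Sup_2_L
3	Frontal_Sup_2_R
4	Frontal_Mid_2_L
5	Frontal_Mid_2_R
6	Frontal_Inf_Oper_L
7	Frontal_Inf_Oper_R
8	Frontal_Inf_Tri_L
9	Frontal_Inf_Tri_R
10	Frontal_Inf_Orb_2_L
11	Frontal_Inf_Orb_2_R
12	Rolandic_Oper_L
13	Rolandic_Oper_R
14	Supp_Motor_Area_L
15	Supp_Motor_Area_R
16	Olfactory_L
17	Olfactory_R
18	Frontal_Sup_Medial_L
19	Frontal_Sup_Medial_R
20	Frontal_Med_Orb_L
21	Frontal_Med_Orb_R
22	Rectus_L
23	Rectus_R
24	OFCmed_L
25	OFCmed_R
26	OFCant_L
27	OFCant_R
28	OFCpost_L
29	OFCpost_R
30	OFClat_L
31	OFClat_R
32	Insula_L
33	Insula_R
34	Cingulate_Ant_L
35	Cingulate_Ant_R
36	Cingulate_Mid_L
37	Cingulate_Mid_R
38	Cingulate_Post_L
39	Cingulate_Post_R
40	Hippocampus_L
41	Hippocampus_R
42	ParaHippocampal_L
43	ParaHippocampal_R
44	Amygdala_L
45	Amygdala_R
46	Calcarine_L
47	Calcarine_R
48	Cuneus_L
49	Cuneus_R
50	Lingual_L
51	Lingual_R
52	Occipital_Sup_L
53	Occipital_Sup_R
54	Occipital_Mid_L
55	Occipital_Mid_R
56	Occipital_Inf_L
57	Occipital_Inf_R
58	Fusiform_L
59	Fusiform_R
60	Postcentral_L
61	Postcentral_R
62	Parietal_Sup_L
63	Parietal_Sup_R
64	Parietal_Inf_L
65	Parietal_Inf_R
66	SupraMarginal_L
67	SupraMarginal_R
68	Angular_L
69	Angular_R
70	Precuneus_L
71	Precuneus_R
72	Paracentral_Lobule_L
73	Paracentral_Lobule_R
74	Caudate_L
75	Caudate_R
76	Putamen_L
77	Putamen_R
78	Pallidum_L
79	Pallidum_R
80	Thalamus_L
81	Thalamus_R
82	Heschl_L
83	Heschl_R
84	Temporal_Sup_L
85	Temporal_Sup_R
86	Temporal_Pole_Sup_L
87	Temporal_Pole_Sup_R
88	Temporal_Mid_L
89	Temporal_Mid_R
90	Temporal_Pole_Mid_L
91	Temporal_Pole_Mid_R
92	Temporal_Inf_L
93	Temporal_Inf_R
94	Cerebelum_Crus1_L
95	Cerebelum_Crus1_R
96	Cerebelum_Crus2_L
97	Cerebelum_Crus2_R
98	Cerebelum_3_L
99	Cerebelum_3_R
100	Cerebelum_4_5_L
101	Cerebelum_4_5_R
102	Cerebelum_6_L
103	Cerebelum_6_R
104	Cerebelum_7b_L
105	Cerebelum_7b_R
106	Cerebelum_8_L
107	Cerebelum_8_R
108	Cerebelum_9_L
109	Cerebelum_9_R
110	Cerebelum_10_L
111	Cerebelum_10_R
112	Vermis_1_2
113	Vermis_3
114	Vermis_4_5
115	Vermis_6
116	Vermis_7
117	Vermis_8
118	Vermis_9
119	Vermis_10
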