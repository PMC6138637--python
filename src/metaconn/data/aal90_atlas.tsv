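index	name	hemisphere	lobe	x	y	z
1	Precentral_L	LEFT	OTHER	-39	-6	51
2	Precentral_R	RIGHT	OTHER	41	-8	52
3	Frontal_Sup_L	LEFT	FRONTAL	-18	35	42
4	Frontal_Sup_R	RIGHT	FRONTAL	22	31	44
5	Frontal_Sup_Orb_L	LEFT	FRONTAL	-17	47	-13
6	Frontal_Sup_Orb_R	RIGHT	FRONTAL	18	48	-14
7	Frontal_Mid_L	LEFT	FRONTAL	-33	33	35
8	Frontal_Mid_R	RIGHT	FRONTAL	38	33	34
9	Frontal_Mid_Orb_L	LEFT	FRONTAL	-31	50	-10
10	Frontal_Mid_Orb_R	RIGHT	FRONTAL	33	53	-11
11	Frontal_Inf_Oper_L	LEFT	FRONTAL	-48	13	19
12	Frontal_Inf_Oper_R	RIGHT	FRONTAL	50	15	21
13	Frontal_Inf_Tri_L	LEFT	FRONTAL	-46	30	14
14	Frontal_Inf_Tri_R	RIGHT	FRONTAL	50	30	14
15	Frontal_Inf_Orb_L	LEFT	FRONTAL	-36	31	-12
16	Frontal_Inf_Orb_R	RIGHT	FRONTAL	41	32	-12
17	Rolandic_Oper_L	LEFT	OTHER	-47	-8	14
18	Rolandic_Oper_R	RIGHT	OTHER	53	-6	15
19	Supp_Motor_Area_L	LEFT	OTHER	-5	5	61
20	Supp_Motor_Area_R	RIGHT	OTHER	9	0	62
21	Olfactory_L	LEFT	OTHER	-8	15	-11
22	Olfactory_R	RIGHT	OTHER	10	16	-11
23	Frontal_Sup_Medial_L	LEFT	FRONTAL	-5	49	31
24	Frontal_Sup_Medial_R	RIGHT	FRONTAL	9	51	30
25	Frontal_Med_Orb_L	LEFT	FRONTAL	-5	54	-7
26	Frontal_Med_Orb_R	RIGHT	FRONTAL	8	52	-7
27	Rectus_L	LEFT	FRONTAL	-5	37	-18
28	Rectus_R	RIGHT	FRONTAL	8	36	-18
29	Insula_L	LEFT	OTHER	-35	7	3
30	Insula_R	RIGHT	OTHER	39	6	2
31	Cingulum_Ant_L	LEFT	OTHER	-4	35	14
32	Cingulum_Ant_R	RIGHT	OTHER	8	37	16
33	Cingulum_Mid_L	LEFT	OTHER	-5	-15	42
34	Cingulum_Mid_R	RIGHT	OTHER	8	-9	40
35	Cingulum_Post_L	LEFT	OTHER	-5	-43	25
36	Cingulum_Post_R	RIGHT	OTHER	7	-42	22
37	Hippocampus_L	LEFT	HIPPOCAMPUS	-25	-21	-10
38	Hippocampus_R	RIGHT	HIPPOCAMPUS	29	-20	-10
39	ParaHippocampal_L	LEFT	OTHER	-21	-16	-21
40	ParaHippocampal_R	RIGHT	OTHER	25	-15	-20
41	Amygdala_L	LEFT	SUBCORTICAL	-23	-1	-17
42	Amygdala_R	RIGHT	SUBCORTICAL	27	1	-18
43	Calcarine_L	LEFT	OCCIPITAL	-7	-79	6
44	Calcarine_R	RIGHT	OCCIPITAL	16	-73	9
45	Cuneus_L	LEFT	OCCIPITAL	-6	-80	27
46	Cuneus_R	RIGHT	OCCIPITAL	14	-79	28
47	Lingual_L	LEFT	OCCIPITAL	-15	-68	-5
48	Lingual_R	RIGHT	OCCIPITAL	16	-67	-4
49	Occipital_Sup_L	LEFT	OCCIPITAL	-17	-84	28
50	Occipital_Sup_R	RIGHT	OCCIPITAL	24	-81	31
51	Occipital_Mid_L	LEFT	OCCIPITAL	-32	-81	16
52	Occipital_Mid_R	RIGHT	OCCIPITAL	37	-80	19
53	Occipital_Inf_L	LEFT	OCCIPITAL	-36	-78	-8
54	Occipital_Inf_R	RIGHT	OCCIPITAL	38	-82	-8
55	Fusiform_L	LEFT	TEMPORAL	-31	-40	-20
56	Fusiform_R	RIGHT	TEMPORAL	34	-39	-20
57	Postcentral_L	LEFT	PARIETAL	-42	-23	49
58	Postcentral_R	RIGHT	PARIETAL	41	-25	53
59	Parietal_Sup_L	LEFT	PARIETAL	-23	-60	59
60	Parietal_Sup_R	RIGHT	PARIETAL	26	-59	62
61	Parietal_Inf_L	LEFT	PARIETAL	-43	-46	47
62	Parietal_Inf_R	RIGHT	PARIETAL	46	-46	50
63	SupraMarginal_L	LEFT	PARIETAL	-56	-34	30
64	SupraMarginal_R	RIGHT	PARIETAL	58	-32	34
65	Angular_L	LEFT	PARIETAL	-44	-61	36
66	Angular_R	RIGHT	PARIETAL	46	-60	39
67	Precuneus_L	LEFT	PARIETAL	-7	-56	48
68	Precuneus_R	RIGHT	PARIETAL	10	-56	44
69	Paracentral_Lobule_L	LEFT	OTHER	-8	-25	70
70	Paracentral_Lobule_R	RIGHT	OTHER	7	-32	68
71	Caudate_L	LEFT	SUBCORTICAL	-11	11	9
72	Caudate_R	RIGHT	SUBCORTICAL	15	12	9
73	Putamen_L	LEFT	SUBCORTICAL	-24	4	2
74	Putamen_R	RIGHT	SUBCORTICAL	28	5	2
75	Pallidum_L	LEFT	SUBCORTICAL	-18	0	0
76	Pallidum_R	RIGHT	SUBCORTICAL	21	0	0
77	Thalamus_L	LEFT	SUBCORTICAL	-11	-18	8
78	Thalamus_R	RIGHT	SUBCORTICAL	13	-18	8
79	Heschl_L	LEFT	TEMPORAL	-42	-19	10
80	Heschl_R	RIGHT	TEMPORAL	46	-17	10
81	Temporal_Sup_L	LEFT	TEMPORAL	-53	-21	7
82	Temporal_Sup_R	RIGHT	TEMPORAL	58	-22	7
83	Temporal_Pole_Sup_L	LEFT	TEMPORAL	-40	15	-20
84	Temporal_Pole_Sup_R	RIGHT	TEMPORAL	48	15	-17
85	Temporal_Mid_L	LEFT	TEMPORAL	-56	-34	-2
86	Temporal_Mid_R	RIGHT	TEMPORAL	57	-37	-1
87	Temporal_Pole_Mid_L	LEFT	TEMPORAL	-36	15	-34
88	Temporal_Pole_Mid_R	RIGHT	TEMPORAL	44	15	-32
89	Temporal_Inf_L	LEFT	TEMPORAL	-50	-28	-23
90	Temporal_Inf_R	RIGHT	TEMPORAL	54	-31	-22
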