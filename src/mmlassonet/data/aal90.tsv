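id	name	abbreviation	x	y	z
1	Precentral_L	PreCG.L	-39	-6	51
2	Precentral_R	PreCG.R	41	-8	52
3	Frontal_Sup_L	SFGdor.L	-18	35	42
4	Frontal_Sup_R	SFGdor.R	22	31	44
5	Frontal_Sup_Orb_L	ORBsup.L	-17	47	-13
6	Frontal_Sup_Orb_R	ORBsup.R	18	48	-14
7	Frontal_Mid_L	MFG.L	-33	33	35
8	Frontal_Mid_R	MFG.R	38	33	34
9	Frontal_Mid_Orb_L	ORBmid.L	-31	50	-10
10	Frontal_Mid_Orb_R	ORBmid.R	33	53	-11
11	Frontal_Inf_Oper_L	IFGoperc.L	-48	13	19
12	Frontal_Inf_Oper_R	IFGoperc.R	50	15	21
13	Frontal_Inf_Tri_L	IFGtriang.L	-46	30	14
14	Frontal_Inf_Tri_R	IFGtriang.R	50	30	14
15	Frontal_Inf_Orb_L	ORBinf.L	-36	31	-12
16	Frontal_Inf_Orb_R	ORBinf.R	41	32	-12
17	Rolandic_Oper_L	ROL.L	-47	-8	14
18	Rolandic_Oper_R	ROL.R	53	-6	15
19	Supp_Motor_Area_L	SMA.L	-5	5	61
20	Supp_Motor_Area_R	SMA.R	9	0	62
21	Olfactory_L	OLF.L	-8	15	-11
22	Olfactory_R	OLF.R	10	16	-11
23	Frontal_Sup_Medial_L	SFGmed.L	-5	49	31
24	Frontal_Sup_Medial_R	SFGmed.R	9	51	30
25	Frontal_Med_Orb_L	ORBsupmed.L	-5	54	-7
26	Frontal_Med_Orb_R	ORBsupmed.R	8	52	-7
27	Rectus_L	REC.L	-5	37	-18
28	Rectus_R	REC.R	8	36	-18
29	Insula_L	INS.L	-35	7	3
30	Insula_R	INS.R	39	6	2
31	Cingulum_Ant_L	ACG.L	-4	35	14
32	Cingulum_Ant_R	ACG.R	8	37	16
33	Cingulum_Mid_L	DCG.L	-5	-15	42
34	Cingulum_Mid_R	DCG.R	8	-9	40
35	Cingulum_Post_L	PCG.L	-5	-43	25
36	Cingulum_Post_R	PCG.R	7	-42	22
37	Hippocampus_L	HIP.L	-25	-21	-10
38	Hippocampus_R	HIP.R	29	-20	-10
39	ParaHippocampal_L	PHG.L	-21	-16	-21
40	ParaHippocampal_R	PHG.R	25	-15	-20
41	Amygdala_L	AMYG.L	-23	-1	-17
42	Amygdala_R	AMYG.R	27	1	-18
43	Calcarine_L	CAL.L	-7	-79	6
44	Calcarine_R	CAL.R	16	-73	9
45	Cuneus_L	CUN.L	-6	-80	27
46	Cuneus_R	CUN.R	14	-79	28
47	Lingual_L	LING.L	-15	-68	-5
48	Lingual_R	LING.R	16	-67	-4
49	Occipital_Sup_L	SOG.L	-17	-84	28
50	Occipital_Sup_R	SOG.R	24	-81	31
51	Occipital_Mid_L	MOG.L	-32	-81	16
52	Occipital_Mid_R	MOG.R	37	-80	19
53	Occipital_Inf_L	IOG.L	-36	-78	-8
54	Occipital_Inf_R	IOG.R	38	-82	-8
55	Fusiform_L	FFG.L	-31	-40	-20
56	Fusiform_R	FFG.R	34	-39	-20
57	Postcentral_L	PoCG.L	-42	-23	49
58	Postcentral_R	PoCG.R	41	-25	53
59	Parietal_Sup_L	SPG.L	-23	-60	59
60	Parietal_Sup_R	SPG.R	26	-59	62
61	Parietal_Inf_L	IPL.L	-43	-46	47
62	Parietal_Inf_R	IPL.R	46	-46	50
63	SupraMarginal_L	SMG.L	-56	-34	30
64	SupraMarginal_R	SMG.R	58	-32	34
65	Angular_L	ANG.L	-44	-61	36
66	Angular_R	ANG.R	46	-60	39
67	Precuneus_L	PCUN.L	-7	-56	48
68	Precuneus_R	PCUN.R	10	-56	44
69	Paracentral_Lobule_L	PCL.L	-8	-25	70
70	Paracentral_Lobule_R	PCL.R	7	-32	68
71	Caudate_L	CAU.L	-11	11	9
72	Caudate_R	CAU.R	15	12	9
73	Putamen_L	PUT.L	-24	4	2
74	Putamen_R	PUT.R	28	5	2
75	Pallidum_L	PAL.L	-18	0	0
76	Pallidum_R	PAL.R	21	0	0
77	Thalamus_L	THA.L	-11	-18	8
78	Thalamus_R	THA.R	13	-18	8
79	Heschl_L	HES.L	-42	-19	10
80	Heschl_R	HES.R	46	-17	10
81	Temporal_Sup_L	STG.L	-53	-21	7
82	Temporal_Sup_R	STG.R	58	-22	7
83	Temporal_Pole_Sup_L	TPOsup.L	-40	15	-20
84	Temporal_Pole_Sup_R	TPOsup.R	48	15	-17
85	Temporal_Mid_L	MTG.L	-56	-34	-2
86	Temporal_Mid_R	MTG.R	57	-37	-1
87	Temporal_Pole_Mid_L	TPOmid.L	-36	15	-34
88	Temporal_Pole_Mid_R	TPOmid.R	44	15	-32
89	Temporal_Inf_L	ITG.L	-50	-28	-23
90	Temporal_Inf_R	ITG.R	54	-31	-22
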