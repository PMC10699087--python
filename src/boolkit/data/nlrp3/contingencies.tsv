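!UID	!Target	!Contingency	!Modifier	!Reference
1	<Signal1>	OR	[LPS]	TLR4 ligand
2	<Signal1>	OR	[Pam3csk4]	TLR1/2 ligand
3	<Signal1>	OR	[IL1]	IL-1R1 ligand
4	<Signal1>	OR	[TNF]	TNFR ligand
5	<Signal1>	OR	[ABagg]	amyloid-beta aggregates
6	<PI34P>	AND	PI_[(3)]-{P}
7	<PI34P>	AND	PI_[(4)]-{P}
8	<AKTpp>	AND	AKT_[(T308)]-{P}
9	<AKTpp>	AND	AKT_[(S473)]-{P}
10	<AKT*>	OR	[SC79]	chemical AKT activator
11	<AKT*>	OR	<AKTpp>
12	<AKTactive>	AND	AKT_[PH]--PI_[head]
13	<AKTactive>	AND	<AKT*>
14	<AKTinhib>	OR	[MK2206]	AKT inhibitor
15	<AKTinhib>	OR	[AKTK179M]	kinase-dead mutation
16	<NLRP3open>	OR	NLRP3_[(NBD)]-{ATP}
17	<NLRP3open>	OR	[nlrp3T346M]	CAPS mutation stabilising the open form
18	<ionicfluxOR>	OR	[Nigericin]	type I trigger
19	<ionicfluxOR>	OR	[extATP]	type I trigger (P2X7)
20	<ionicfluxOR>	OR	[PoreToxin]	type I trigger (pore-forming toxins)
21	<ionicfluxOR>	OR	[gDpmPoreFormation]	gasdermin D feedback
22	<ETCiOR>	OR	[Imiquimod]	type III trigger
23	<ETCiOR>	OR	[CL097]	type III trigger
24	<lowATPOR>	OR	[mitKgradImpaired]
25	<lowATPOR>	OR	[mitHgradImpaired]
26	<TGNdispersalOR>	OR	[AcidDefect]
27	<TGNdispersalOR>	OR	[LMP]
28	<NLRP3membOR>	OR	NLRP3_[KMKK]--PI_[head]
29	<NLRP3membOR>	OR	CL_[lrrCL]--NLRP3_[cl]
30	<centroPI4P>	AND	NLRP3_[KMKK]--PI_[head]
31	<centroPI4P>	AND	[CentrosomalPI4P]
32	<centroCL>	AND	CL_[lrrCL]--NLRP3_[cl]
33	<centroCL>	AND	[CentrosomalCL]
34	<CentrosomalNLRP3OR>	OR	<centroPI4P>
35	<CentrosomalNLRP3OR>	OR	<centroCL>
36	<gDpmPoreOR>	OR	GasderminD_[nt]--PI_[gdbd]
37	<gDpmPoreOR>	OR	GasderminD_[nt]--PS_[gdbd]
38	<NLRP3autophagyOR>	OR	NLRP3_[ub]--SQSTM1_[UBA]
39	<NLRP3autophagyOR>	OR	NLRP3_[t20]--TRIM20_[bd]
40	<Casp1fil>	AND	ASC_[t20]--TRIM20_[asc]
41	<Casp1fil>	AND	ASC_[card]--Caspase1_[card1]
45	[Signal1]	!	<Signal1>
46	[ionicflux]	!	<ionicfluxOR>
47	[Kefflux]	!	[ionicflux]
48	[Kefflux]	x	[extK]	suppression by high external KCl
49	[lowintK]	!	[Kefflux]
50	[mitKgradImpaired]	!	[lowintK]	secondary mitochondrial K+ gradient
51	[ETCi]	!	<ETCiOR>
52	[mitHgradImpaired]	!	[ETCi]
53	[lowATP]	!	<lowATPOR>
54	[HighLysoK]	!	[Type2Trigger]	lysosomal K+ influx
55	[LMP]	!	[HighLysoK]
56	[LMP]	x	[extK]	rescue by high external KCl
57	[AcidDefect]	!	[lowATP]
58	[TGNdispersal]	!	<TGNdispersalOR>
59	[PI4Pacc]	!	[TGNdispersal]
60	[CentrosomalPI4P]	!	[PI4Pacc]
61	[CLexposure]	!	[MMPT]	outer-membrane permeabilisation
62	[CentrosomalCL]	!	[CLexposure]
63	[NLRP3memb]	!	<NLRP3membOR>
64	[CentrosomalNLRP3]	!	<CentrosomalNLRP3OR>
65	[BacterialKilling]	!	CL_[gdbd]--GasderminD_[nt]
66	[gDpmPoreFormation]	!	<gDpmPoreOR>
67	[Pyroptosis]	!	[gDpmPoreFormation]
68	[IL1Brelease]	!	[gDpmPoreFormation]
69	[IL1Brelease]	!	IL1b_[(pro)]-{truncated}
70	[IL18release]	!	[gDpmPoreFormation]
71	[IL18release]	!	IL18_[(pro)]-{truncated}
80	Pol_trsc_NLRP3	!	<Signal1>
81	Pol_trsc_IL1b	!	<Signal1>
82	Tbk1_P+_AKT_[(T308)]	!	<Signal1>
83	AKT_[PH]_ppi+_PI_[head]	!	<PI34P>
84	AKT_P+_NLRP3_[(S5)]	!	<AKTactive>
85	AKT_P+_NLRP3_[(S5)]	x	<AKTinhib>
86	PP2Aca_P-_NLRP3_[(S5)]	x	[OKA]	okadaic acid
87	JNK1_P+_NLRP3_[(S198)]	!	<Signal1>
88	BRCC36_[bd]_ppi+_NLRP3_[nb36]	!	NLRP3_[(S198)]-{P}
89	G5_[dub]_ppi+_BRCC36_[G5]	!	[G5]	deubiquitinase inhibitor
90	NEK7_[clobe]_ppi+_NLRP3_[HD2LRR]	!	NLRP3_[(S806)]-{0}
91	NEK7_[clobe]_ppi+_NLRP3_[HD2LRR]	!	NLRP3_[(Y861)]-{0}
92	NEK7_[clobe]_ppi+_NLRP3_[HD2LRR]	!	[CentrosomalNLRP3]
93	NEK7_[clobe]_ppi+_NLRP3_[HD2LRR]	x	[nlrp3S806D]	phosphomimic mutation
94	BRCC36_ub63-_NLRP3_[(lrr)]	!	BRCC36_[bd]--NLRP3_[nb36]
95	BRCC36_ub63-_NLRP3_[(lrr)]	!	NEK7_[clobe]--NLRP3_[HD2LRR]
96	BRCC36_ub63-_NLRP3_[(lrr)]	!	NLRP3_[(NBD)]-{ADP}	closed conformation
97	BRCC36_ub63-_NLRP3_[(lrr)]	x	BRCC36_[G5]--G5_[dub]
98	MCC950_[bd]_ppi+_NLRP3_[NOD]	!	[MCC950]
99	PKA_P+_NLRP3_[(S295)]	x	[nlrp3D305G]	CAPS mutation
100	NLRP3_aBind_NLRP3_[(NBD)]	!	[NLRP3memb]
101	NLRP3_aEx_NLRP3_[(NBD)]	!	[NLRP3memb]
102	NLRP3_aEx_NLRP3_[(NBD)]	!	NLRP3_[(S295)]-{0}
103	NLRP3_aEx_NLRP3_[(NBD)]	x	MCC950_[bd]--NLRP3_[NOD]
104	NLRP3_[KMKK]_ppi+_PI_[head]	!	PI_[(4)]-{P}
105	NLRP3_[KMKK]_ppi-_PI_[head]	!	NLRP3_[(NBD)]-{ADP}
106	NLRP3_[cl]_i_CL_[lrrCL]	!	[CLexposure]
107	NLRP3_[NACHT]_ppi+_NLRP3_[NACHT]	!	<NLRP3open>
108	NLRP3_[NACHT]_ppi+_NLRP3_[NACHT]	!	NEK7_[clobe]--NLRP3_[HD2LRR]
109	NLRP3_[NACHT]_ppi+_NLRP3_[NACHT]	!	NLRP3_[(lrr)]-{0}
110	NLRP3_[pydA]_ppi+_NLRP3_[pydB]	!	NLRP3_[NACHT]--NLRP3_[NACHT]
111	NLRP3_[pydA]_ppi+_NLRP3_[pydB]	!	NLRP3_[(S5)]-{0}
112	ASC_[pydA]_ppi+_NLRP3_[pydB]	!	NLRP3_[pydA]--NLRP3_[pydB]
113	ASC_[pydA]_ppi+_ASC_[pydB]	!	ASC_[pydA]--NLRP3_[pydB]
114	Caspase1_[card1]_ppi+_ASC_[card]	!	ASC_[pydA]--ASC_[pydB]
115	Caspase1_[card1]_ppi+_Caspase1_[card2]	!	ASC_[card]--Caspase1_[card1]
116	Caspase1_cut_Caspase1_[(pro)]	!	Caspase1_[card1]--Caspase1_[card2]
117	Caspase1_cut_IL1b_[(pro)]	!	Caspase1_[(pro)]-{truncated}
118	Caspase1_cut_IL18_[(pro)]	!	Caspase1_[(pro)]-{truncated}
119	Caspase1_cut_GasderminD_[(D275)]	!	Caspase1_[(pro)]-{truncated}
120	Caspase4_cut_GasderminD_[(D275)]	!	Caspase4_[(pro)]-{truncated}
121	Caspase5_cut_GasderminD_[(D275)]	!	Caspase5_[(pro)]-{truncated}
122	GasderminD_[nt]_i_PI_[gdbd]	!	GasderminD_[(D275)]-{truncated}
123	GasderminD_[nt]_i_PS_[gdbd]	!	GasderminD_[(D275)]-{truncated}
124	GasderminD_[nt]_i_CL_[gdbd]	!	GasderminD_[(D275)]-{truncated}
125	Caspase4_[lps]_ppi+_LPS_[lbp]	!	[intLPS]
126	Caspase4_[dim]_ppi+_Caspase4_[dim]	!	Caspase4_[lps]--LPS_[lbp]
127	Caspase4_cut_Caspase4_[(pro)]	!	Caspase4_[dim]--Caspase4_[dim]
128	Caspase5_[lps]_ppi+_LPS_[lbp]	!	[intLPS]
129	Caspase5_[dim]_ppi+_Caspase5_[dim]	!	Caspase5_[lps]--LPS_[lbp]
130	Caspase5_cut_Caspase5_[(pro)]	!	Caspase5_[dim]--Caspase5_[dim]
131	TRIM31_ub48+_NLRP3_[(K496)]	!	NLRP3_[(S5)]-{0}
132	CblB_[UBA]_ppi+_NLRP3_[lrrUb]	!	NLRP3_[(lrr)]-{ub63}
133	CblB_ub48+_NLRP3_[(K496)]	!	CblB_[UBA]--NLRP3_[lrrUb]
134	CblB_ub48+_NLRP3_[(K496)]	!	NLRP3_[(S5)]-{0}
135	Proteasome_deg_NLRP3	!	NLRP3_[(K496)]-{ub48}
136	SQSTM1_[UBA]_ppi+_NLRP3_[ub]	!	NLRP3_[(lrr)]-{ub63}
137	TRIM20_[bd]_ppi+_NLRP3_[t20]	!	ASC_[pydA]--NLRP3_[pydB]
138	TRIM20_[asc]_ppi+_ASC_[t20]	!	TRIM20_[bd]--NLRP3_[t20]
139	LysosomalProteases_deg_NLRP3	!	<NLRP3autophagyOR>
140	LysosomalProteases_deg_ASC	!	TRIM20_[asc]--ASC_[t20]
141	LysosomalProteases_deg_Caspase1	!	<Casp1fil>
175	RNF125_ub63+_NLRP3_[(lrr)]	x	[miniNLRP3]	LRR truncation
176	BRCC36_ub63-_NLRP3_[(lrr)]	x	[miniNLRP3]	LRR truncation
177	CblB_[UBA]_ppi+_NLRP3_[lrrUb]	x	[miniNLRP3]	LRR truncation
178	uKin_P+_NLRP3_[(Y861)]	x	[miniNLRP3]	LRR truncation
179	PTPN22_P-_NLRP3_[(Y861)]	x	[miniNLRP3]	LRR truncation
180	CSNK1A1_P+_NLRP3_[(S806)]	x	[miniNLRP3]	LRR truncation
181	X_P-_NLRP3_[(S806)]	x	[miniNLRP3]	LRR truncation
182	NLRP3_[cl]_i_CL_[lrrCL]	x	[miniNLRP3]	LRR truncation
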