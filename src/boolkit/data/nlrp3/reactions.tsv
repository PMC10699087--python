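!UID	!Reaction	!Reference
1	Pol_trsc_NLRP3	NFkB-dependent transcription of NLRP3
2	Pol_trsc_IL1b	NFkB-dependent transcription of pro-IL-1b
3	Ribo_trsl_NLRP3	translation of NLRP3 mRNA
4	Ribo_trsl_IL1b	translation of pro-IL-1b mRNA
5	X_deg_NLRP3mRNA	mRNA turnover (placeholder catalyst)
6	X_deg_IL1bmRNA	mRNA turnover (placeholder catalyst)
7	Tbk1_P+_AKT_[(T308)]	priming-dependent AKT activation
8	Pdk1_P+_AKT_[(T308)]	constitutive AKT activation loop
9	mTORC2_P+_AKT_[(S473)]	constitutive AKT activation loop
10	PP2A_P-_AKT_[(T308)]	AKT deactivation
11	X_P-_AKT_[(S473)]	unknown phosphatase (placeholder)
12	PI3K_P+_PI_[(3)]	phosphoinositide 3-phosphorylation
13	PI4K_P+_PI_[(4)]	phosphoinositide 4-phosphorylation
14	AKT_[PH]_ppi+_PI_[head]	AKT recruitment to PI(3,4)P2 / PI(3,4,5)P3
15	AKT_P+_NLRP3_[(S5)]	inhibitory Ser5 phosphorylation
16	PP2Aca_P-_NLRP3_[(S5)]	Ser5 dephosphorylation
17	JNK1_P+_NLRP3_[(S198)]	priming-dependent licensing phosphorylation
18	BRCC36_[bd]_ppi+_NLRP3_[nb36]	BRCC36 recruitment to NLRP3
19	G5_[dub]_ppi+_BRCC36_[G5]	deubiquitinase inhibitor binding
20	CSNK1A1_P+_NLRP3_[(S806)]	constitutive Ser806 phosphorylation
21	X_P-_NLRP3_[(S806)]	unknown phosphatase (placeholder)
22	uKin_P+_NLRP3_[(Y861)]	unknown tyrosine kinase (placeholder)
23	PTPN22_P-_NLRP3_[(Y861)]	Tyr861 dephosphorylation
24	NEK7_[clobe]_ppi+_NLRP3_[HD2LRR]	centrosomal NEK7 recruitment
25	BRCC36_ub63-_NLRP3_[(lrr)]	K63 deubiquitylation of the LRR domain
26	MCC950_[bd]_ppi+_NLRP3_[NOD]	inhibitor binding to the NACHT cleft
27	PKA_P+_NLRP3_[(S295)]	Ser295 phosphorylation
28	PKD_P+_NLRP3_[(S295)]	Ser295 phosphorylation
29	X_P-_NLRP3_[(S295)]	unknown phosphatase (placeholder)
30	NLRP3_aBind_NLRP3_[(NBD)]	ATP binding to the empty NBD
31	NLRP3_aEx_NLRP3_[(NBD)]	ADP-to-ATP exchange
32	NLRP3_aHy_NLRP3_[(NBD)]	ATP hydrolysis
33	NLRP3_[KMKK]_ppi+_PI_[head]	polybasic-motif binding to PI(4)P
34	NLRP3_[KMKK]_ppi-_PI_[head]	membrane release of ADP-bound NLRP3
35	NLRP3_[cl]_i_CL_[lrrCL]	LRR-domain binding to exposed cardiolipin
36	NLRP3_[NACHT]_ppi+_NLRP3_[NACHT]	NACHT-domain self-association
37	NLRP3_[pydA]_ppi+_NLRP3_[pydB]	PYD filament nucleation
38	ASC_[pydA]_ppi+_NLRP3_[pydB]	ASC recruitment to the PYD filament
39	ASC_[pydA]_ppi+_ASC_[pydB]	ASC PYD polymerisation
40	Caspase1_[card1]_ppi+_ASC_[card]	caspase-1 recruitment via CARD
41	Caspase1_[card1]_ppi+_Caspase1_[card2]	caspase-1 CARD filament
42	Caspase1_cut_Caspase1_[(pro)]	proximity-induced autoprocessing
43	Caspase1_cut_IL1b_[(pro)]	pro-IL-1b maturation
44	Caspase1_cut_IL18_[(pro)]	pro-IL-18 maturation
45	Caspase1_cut_GasderminD_[(D275)]	gasdermin D activation
46	Caspase4_cut_GasderminD_[(D275)]	non-canonical gasdermin D activation
47	Caspase5_cut_GasderminD_[(D275)]	non-canonical gasdermin D activation
48	GasderminD_[nt]_i_PI_[gdbd]	pore formation on phosphoinositides
49	GasderminD_[nt]_i_PS_[gdbd]	pore formation on phosphatidylserine
50	GasderminD_[nt]_i_CL_[gdbd]	bactericidal cardiolipin targeting
51	Caspase4_[lps]_ppi+_LPS_[lbp]	cytoplasmic LPS sensing
52	Caspase4_[dim]_ppi+_Caspase4_[dim]	LPS-induced dimerisation
53	Caspase4_cut_Caspase4_[(pro)]	trans-autoprocessing
54	Caspase5_[lps]_ppi+_LPS_[lbp]	cytoplasmic LPS sensing
55	Caspase5_[dim]_ppi+_Caspase5_[dim]	LPS-induced dimerisation
56	Caspase5_cut_Caspase5_[(pro)]	trans-autoprocessing
57	RNF125_ub63+_NLRP3_[(lrr)]	K63 ubiquitylation of the LRR domain
58	TRIM31_ub48+_NLRP3_[(K496)]	constitutive K48 ubiquitylation
59	CblB_[UBA]_ppi+_NLRP3_[lrrUb]	CblB recruitment to K63 chains
60	CblB_ub48+_NLRP3_[(K496)]	K48 ubiquitylation after CblB binding
61	Proteasome_deg_NLRP3	proteasomal degradation
62	SQSTM1_[UBA]_ppi+_NLRP3_[ub]	autophagy receptor binding
63	TRIM20_[bd]_ppi+_NLRP3_[t20]	precision-autophagy recognition
64	TRIM20_[asc]_ppi+_ASC_[t20]	precision-autophagy recognition
65	LysosomalProteases_deg_NLRP3	autophagosomal degradation
66	LysosomalProteases_deg_ASC	autophagosomal degradation
67	LysosomalProteases_deg_Caspase1	autophagosomal degradation
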