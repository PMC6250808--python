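group	gene	pearson_r	p_value	fdr	style
NN	IL2RA	0.9732955	9.98E-06	0.0001717	Positive
NN	PRKCQ	0.9687537	1.72E-05	0.0002295	Positive
NN	CD28	0.9636073	2.92E-05	0.0003181	Positive
NN	RRM2	0.9579704	4.81E-05	0.0004146	Positive
NN	CCR5	0.9491639	9.28E-05	0.0006202	Positive
NN	SH2D1A	0.9451843	0.0001203	0.0007168	Positive
NN	SOD2	0.9420219	0.000146	0.000804	Positive
NN	CDK1	0.9395096	0.0001689	0.0008682	Positive
NN	EIF2AK2	0.9374203	0.0001898	0.0009311	Positive
NN	STAT1	0.935628	0.0002092	0.0009775	Positive
NN	IL7R	0.9274773	0.0003149	0.0012596	Positive
NN	PTPRC	0.9266246	0.0003278	0.0012927	Positive
NN	CCNB2	0.9249148	0.0003547	0.0013297	Positive
NN	TLR4	0.9172249	0.0004951	0.0016521	Positive
NN	CD86	0.9127902	0.0005917	0.0018396	Positive
NN	SELE	0.90586	0.0007679	0.0021744	Positive
NN	CCR1	0.9043284	0.0008113	0.0022361	Positive
NN	ACSL4	0.8998301	0.0009485	0.0024332	Positive
NN	CHEK1	0.897294	0.0010326	0.0025454	Positive
NN	IFIH1	0.8901775	0.0012961	0.0029215	Positive
NN	IL6ST	0.8842571	0.0015483	0.0032586	Positive
NN	CASP8	0.8832669	0.0015936	0.003319	Positive
NN	TLR3	0.8818203	0.0016613	0.0033809	Positive
NN	IL19	0.8780748	0.001846	0.0036114	Positive
NN	FCGR1C	0.8780748	0.001846	0.0036114	Positive
NN	ATR	0.8765252	0.0019264	0.0036989	Positive
NN	JAK2	0.8721792	0.0021647	0.0039831	Positive
NN	FAR1	0.8709298	0.0022368	0.0040843	Positive
NN	CCNB1	0.8690707	0.0023472	0.0042117	Positive
NN	AOX1	0.8679496	0.0024155	0.0042772	Positive
NN	CTLA4	0.8556067	0.003261	0.0051653	Positive
NN	TLR6	0.854854	0.0033184	0.0052137	Positive
NN	IL12RB1	0.8535532	0.0034191	0.0052649	Positive
NN	PDCD1LG2	0.8534694	0.0034256	0.0052681	Positive
NN	ATM	0.8529131	0.0034694	0.0052953	Positive
NN	CD3G	0.8522091	0.0035253	0.0053394	Positive
NN	STAT4	0.8517455	0.0035625	0.0053668	Positive
NN	TNFSF14	0.8484067	0.0038381	0.0056231	Positive
NN	TLR1	0.8479869	0.0038737	0.0056293	Positive
NN	UBE2T	0.8459649	0.0040487	0.0058049	Positive
NN	POLK	0.8386417	0.0047275	0.0063276	Positive
NN	BRIP1	0.8381076	0.0047799	0.0063603	Positive
NN	IL26	0.8170625	0.0071733	0.0081403	Positive
NN	IL17A	0.8052876	0.0088147	0.0092264	Positive
NN	CD80	0.8052343	0.0088226	0.0092292	Positive
NN	TNFSF8	0.8038217	0.0090353	0.0093678	Positive
NN	CCL4	0.7989072	0.0098021	0.0098881	Positive
NN	CD209	0.9464572	0.000111	0.0006948	Positive
NN	CD226	0.8807744	0.0017115	0.0034349	Positive
NN	CXCL1	0.8978401	0.0010141	0.0025218	Positive
NN	CYP7B1	0.9328796	0.0002415	0.0010628	Positive
NN	FANCI	0.9250662	0.0003522	0.0013281	Positive
NN	ICOS	0.9539927	6.57E-05	0.0004822	Positive
NN	IFN-γ	0.8780748	0.001846	0.0036114	Positive
NN	PIK3CG	0.956161	5.56E-05	0.0004454	Positive
NN	REV3L	0.9490468	9.35E-05	0.0006202	Positive
PP	EEF1G	-0.675341	0.002101	0.0037489	Negative
PP	IL12B	0.901116	3.36E-07	9.64E-06	Positive
PP	CCL20	0.8556256	5.97E-06	7.67E-05	Positive
PP	CCL7	0.7927733	8.72E-05	0.0004859	Positive
PP	DDX58	0.7621884	0.0002362	0.0009399	Positive
PP	FOS	0.7618061	0.0002389	0.0009452	Positive
PP	IL19	0.664267	0.0026406	0.0043512	Positive
PP	IL1RAP	0.6642463	0.0026417	0.0043512	Positive
PP	IFIH1	0.6626158	0.00273	0.0044301	Positive
PP	STAT1	0.6597544	0.0028909	0.0045988	Positive
PP	CXCL10	0.6595464	0.0029029	0.0046016	Positive
PP	CXCL11	0.6376404	0.004416	0.0060023	Positive
PP	NOS2	0.628715	0.0051931	0.0066592	Positive
PP	CXCL1	0.6198472	0.006072	0.0072939	Positive
PP	CXCL2	0.6630916	0.002704	0.0044047	Positive
PP	LOC100288533	0.6543663	0.003215	0.0048891	Positive
PP	LOC642934	0.6395765	0.0042606	0.0058708	Positive
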