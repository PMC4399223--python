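clone_id	gene	logFC	logCPM	PValue	FDR
V2LMM_6871	MYOG	-2.5393	9.6584	5.24E-39	4.61E-37
V2LMM_68084	ASAP1	1.2699	13.5019	7.53E-29	6.62E-27
V2LMM_63192	LASS6	-1.5047	12.8189	3.47E-23	3.06E-21
V2LMM_64405	NR0B1	-1.2213	12.6156	3.74E-14	3.29E-12
V2LMM_189334	SOX21	0.7841	14.1110	7.57E-11	6.66E-09
V2LMM_82812	Id1	-0.4067	14.0413	1.58E-10	9.96E-09
V2LMM_73029	Myst1	-0.3976	13.7299	4.37E-10	1.38E-08
V2LMM_62263	TBP	-0.9262	6.8162	5.90E-10	2.60E-08
V2LMM_25195	TCEA2	-0.9252	13.0207	6.44E-10	2.69E-08
V2LMM_13506	NKX3-1	-0.9163	13.0783	9.16E-10	2.69E-08
V2LMM_54422	POU1F1	-0.9631	12.8253	1.91E-09	8.39E-08
V2LMM_9553	FOXN1	-1.0459	12.0477	8.86E-09	3.90E-07
V2LMM_259235	FOXC2	0.6794	11.6227	3.67E-08	1.61E-06
V2LMM_53719	TEF	-0.7084	12.9529	3.54E-08	2.24E-06
V2LMM_27467	NFE2L1	-0.7027	12.1790	5.10E-08	2.24E-06
V2LMM_937	MNT	0.8370	13.6556	1.60E-07	4.71E-06
V2LMM_20404	MAFG	0.7503	14.4488	4.96E-07	1.09E-05
V2LMM_218286	SOX9	0.5992	14.6443	5.34E-07	1.57E-05
V2LMM_29411	Ezh2	0.3074	13.6843	1.37E-06	2.89E-05
V2LMM_64907	NR1H3	-0.6947	13.0997	3.26E-06	5.74E-05
V2LMM_226932	NOTCH2	-0.7216	12.6071	7.35E-07	6.47E-05
V2LMM_22166	NR1H4	0.6672	14.0499	7.62E-06	1.12E-04
V2LMM_70598	Klf4	-0.2842	13.7153	7.81E-06	1.23E-04
V2LMM_29885	Lmo2	-0.2790	13.3138	1.25E-05	1.57E-04
V2LMM_85045	ZFP449	-0.5770	13.6233	6.17E-06	1.81E-04
V2LMM_27178	TRPS1	-0.7064	12.9042	9.70E-06	2.13E-04
V2LMM_7277	NRARP	0.5023	13.3971	8.02E-06	2.35E-04
V2LMM_71087	LEF1	-0.6382	13.1210	1.87E-05	2.35E-04
V2LMM_37331	OVOL2	-0.4958	12.5577	1.11E-05	2.45E-04
V2LMM_82311	FOXJ1	-0.4883	13.7075	1.41E-05	2.48E-04
V2LMM_30422	Ezh2	0.2667	13.9399	2.73E-05	2.87E-04
V2LMM_86479	HLF	0.6524	13.6835	6.89E-06	3.03E-04
V2LMM_73715	KLF5	-0.6192	12.8163	3.27E-05	3.60E-04
V2LMM_77459	Tcf4	-0.2612	13.7487	4.01E-05	3.61E-04
V2LMM_87315	ANKRD46	0.6747	13.9989	2.27E-05	3.99E-04
V2LMM_249987	ANKRD33	0.5109	14.5653	1.82E-05	4.00E-04
V2LMM_34449	THRB	0.6078	13.7210	4.51E-05	4.32E-04
V2LMM_34394	MRG2	0.6048	13.8720	4.91E-05	4.32E-04
V2LMM_71843	TCF19	-0.5495	13.0225	6.03E-06	5.31E-04
V2LMM_162758	ETS1	0.5252	13.3887	1.45E-05	6.38E-04
V2LMM_103225	Rbbp8	0.2503	13.5222	8.51E-05	6.70E-04
V2LMM_3550	TCF21	0.4517	13.0423	5.97E-05	8.76E-04
V2LMM_61869	TBP	-0.6028	13.2274	3.29E-05	9.64E-04
V2LMM_110117	NFATC3	-0.7358	13.2152	4.56E-05	1.34E-03
V2LMM_70871	NR1I3	-0.6202	13.2914	9.95E-05	1.36E-03
V2LMM_196851	GATA6	0.6165	13.4939	1.08E-04	1.36E-03
V2LMM_86811	Klf8	-0.2331	14.0270	2.43E-04	1.61E-03
V2LMM_14204	Cbx4	0.2323	14.0165	2.55E-04	1.61E-03
V2LMM_103224	Rbbp8	-0.2249	13.7322	4.06E-04	2.33E-03
V2LMM_2021	MTA3	0.5498	13.3661	2.69E-05	2.37E-03
V2LMM_18790	CLOCK	0.6957	14.2333	1.13E-04	2.49E-03
V2LMM_89022410018	C20RIK	-0.4430	13.8888	1.46E-04	2.57E-03
V2LMM_7952	NR2C1	0.6810	13.8576	1.57E-04	2.76E-03
V2LMM_65378	E2F6	0.4731	12.6660	9.67E-05	2.84E-03
V2LMM_14131	Id3	0.2176	14.1862	6.16E-04	3.23E-03
V2LMM_4616	Cbx4	0.2158	14.2122	6.73E-04	3.26E-03
V2LMM_81587	Klf9	-0.2144	13.9803	7.36E-04	3.31E-03
V2LMM_50581	NR2F2	-0.5745	12.8242	3.14E-04	3.45E-03
V2LMM_71013	HNRPAB	-0.5309	13.3310	8.03E-05	3.53E-03
V2LMM_71313	CML3	-0.6586	13.3786	2.59E-04	3.80E-03
V2LMM_46526	PROX1	0.6463	13.6892	3.35E-04	4.21E-03
V2LMM_63443	MAFB	-0.4007	13.4709	3.65E-04	4.59E-03
V2LMM_75410	ASB4	-0.3952	13.3161	4.41E-04	4.85E-03
V2LMM_87318	ANKRD46	0.3883	13.7227	5.46E-04	5.11E-03
V2LMM_886506430502	M16RIK	-0.3867	13.5604	5.81E-04	5.11E-03
V2LMM_194038	HOXD8	0.4901	13.8093	1.84E-04	5.39E-03
V2LMM_71230	NR1I3	-0.6275	12.9976	5.00E-04	5.50E-03
V2LMM_79666	PAX8	-0.5296	13.7022	2.58E-04	5.67E-03
V2LMM_64571	GCDH	0.4455	13.2693	2.62E-04	5.76E-03
V2LMM_50262	VDR	0.5204	13.8960	3.27E-04	5.76E-03
V2LMM_66887	LASS4	-0.4153	13.1732	3.99E-04	5.85E-03
V2LMM_71060	GTF2H4	-0.4379	13.3758	3.04E-04	6.58E-03
V2LMM_5760	MYC	0.4271	13.4915	4.15E-04	6.58E-03
V2LMM_6641	PYCARD	0.4248	13.2027	4.49E-04	6.58E-03
V2LMM_29358	TBX20	-0.5067	13.3472	4.76E-04	6.98E-03
V2LMM_212338	PPP1R16B	0.3734	13.6841	8.86E-04	7.09E-03
V2LMM_68781	OTX1	-0.6004	13.2971	8.58E-04	8.39E-03
V2LMM_71737	HOXA5	0.4088	13.7302	7.23E-04	9.08E-03
V2LMM_67978	LASS4	0.3995	12.8183	9.89E-04	9.91E-03
V2LMM_62940	IRX6	-0.3977	13.5485	1.01E-03	9.91E-03
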