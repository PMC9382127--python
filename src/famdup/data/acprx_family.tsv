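gene_name	accession	chromosome	start	end	orf_len	exon_count	aa_len	mw_kda	pi
AcPRX1	Aco006655	LG01	22942404	22945339	978	3	325	34.76	4.98
AcPRX2	Aco021354	LG01	10118322	10124972	1059	4	352	37.51	4.82
AcPRX3	Aco021355	LG01	10152822	10159776	1062	5	353	37.99	5.44
AcPRX4	Aco021357	LG01	10182978	10185914	993	4	330	34.94	4.61
AcPRX5	Aco022453	LG01	5181655	5183616	1014	2	337	35.61	6.59
AcPRX6	Aco000925	LG02	15616393	15618018	1056	4	351	38.15	4.99
AcPRX7	Aco020478	LG02	9486642	9488956	990	4	329	35.53	4.69
AcPRX8	Aco020482	LG02	9502096	9508514	993	4	330	35.88	6.59
AcPRX9	Aco011877	LG03	13191903	13199186	2094	11	697	75.87	4.81
AcPRX10	Aco014075	LG03	128210	129408	966	2	321	34.88	6.71
AcPRX11	Aco014076	LG03	123997	125071	930	2	309	33.03	5.28
AcPRX12	Aco002056	LG04	5183006	5187859	996	4	331	36.44	8.69
AcPRX13	Aco002344	LG04	2268585	2275634	1752	6	583	62.0	7.16
AcPRX14	Aco011124	LG04	13559958	13561759	975	3	324	34.67	4.61
AcPRX15	Aco011125	LG04	13553572	13555336	936	4	311	33.34	6.52
AcPRX16	Aco011128	LG04	13524180	13526013	963	4	320	34.36	6.8
AcPRX17	Aco014948	LG04	10852102	10854365	867	5	288	30.39	9.21
AcPRX18	Aco021983	LG04	181855	183224	963	4	320	34.28	9.12
AcPRX19	Aco021984	LG04	190356	192628	993	2	330	36.14	9.28
AcPRX20	Aco023522	LG04	374033	376168	993	2	330	36.09	9.27
AcPRX21	Aco023523	LG04	381622	383417	987	3	328	35.15	9.18
AcPRX22	Aco004317	LG05	2129882	2143830	3060	10	1019	109.73	8.74
AcPRX23	Aco004613	LG05	4458890	4468179	1467	7	488	52.01	6.06
AcPRX24	Aco004784	LG05	5778917	5781088	960	4	319	34.87	5.36
AcPRX25	Aco002775	LG06	11491541	11493377	1068	3	355	39.02	5.2
AcPRX26	Aco002920	LG06	12578625	12580313	1014	2	337	36.47	8.04
AcPRX27	Aco003045	LG06	13446497	13448722	999	4	332	36.19	4.99
AcPRX28	Aco021646	LG06	3277357	3281208	999	4	332	36.19	8.39
AcPRX29	Aco004906	LG07	711110	714125	987	4	328	34.98	6.8
AcPRX30	Aco014483	LG07	13942612	13950563	1971	14	656	73.27	5.57
AcPRX31	Aco014484	LG07	13930364	13942392	2229	9	742	82.31	8.49
AcPRX32	Aco014486	LG07	13917358	13919006	987	4	328	36.41	7.06
AcPRX33	Aco016652	LG08	10748165	10759910	1989	8	662	70.55	4.87
AcPRX34	Aco022304	LG08	12736030	12741485	1668	7	555	59.63	5.83
AcPRX35	Aco008544	LG09	630761	632783	990	4	329	35.57	5.06
AcPRX36	Aco008990	LG09	12648397	12649951	987	3	328	36.57	8.43
AcPRX37	Aco009079	LG09	13183005	13184814	1026	3	341	37.16	4.9
AcPRX38	Aco015772	LG09	10764795	10767222	999	4	332	35.59	7.5
AcPRX39	Aco009743	LG10	64021	70344	1521	7	506	55.56	9.17
AcPRX40	Aco010007	LG10	2135816	2138014	951	3	316	34.21	5.89
AcPRX41	Aco010009	LG10	2138049	2158166	2760	11	919	98.4	7.93
AcPRX42	Aco020332	LG10	12894588	12902324	1092	5	363	39.52	8.71
AcPRX43	Aco020334	LG10	12882382	12885182	1044	4	347	38.36	5.17
AcPRX44	Aco005737	LG11	12540906	12548249	1545	5	514	56.57	9.92
AcPRX45	Aco016519	LG11	383223	387691	1011	4	336	36.65	8.08
AcPRX46	Aco012522	LG13	1786966	1789080	957	4	318	34.11	6.05
AcPRX47	Aco012524	LG13	1805368	1809238	960	4	319	34.05	8.09
AcPRX48	Aco013666	LG13	11351548	11352919	1050	2	349	38.04	6.67
AcPRX49	Aco006432	LG14	2360239	2362650	999	4	332	35.12	4.61
AcPRX50	Aco014874	LG14	344806	346770	1053	4	350	38.81	8.46
AcPRX51	Aco013384	LG15	10676947	10698878	2886	12	961	103.55	5.97
AcPRX52	Aco006230	LG16	7715989	7722953	1104	3	367	39.66	8.85
AcPRX53	Aco021127	LG16	508904	513657	969	4	322	34.98	8.33
AcPRX54	Aco026779	LG16	183852	190883	999	5	332	35.78	4.57
AcPRX55	Aco003198	LG17	1062168	1065621	1083	3	360	38.62	8.47
AcPRX56	Aco003200	LG17	1070224	1073010	1083	3	360	38.71	8.58
AcPRX57	Aco003320	LG17	1983887	1985624	1002	4	333	36.02	5.1
AcPRX58	Aco001617	LG18	9253311	9270632	2364	12	787	83.69	4.95
AcPRX59	Aco001618	LG18	9248026	9252038	1914	6	637	67.86	4.52
AcPRX60	Aco008430	LG19	10318327	10320385	1020	4	339	38.22	8.53
AcPRX61	Aco008465	LG19	10590430	10593279	1002	4	333	36.69	6.94
AcPRX62	Aco015271	LG20	10156870	10159414	1068	2	355	37.94	8.92
AcPRX63	Aco019704	LG20	8345185	8348513	1014	4	337	35.72	4.7
AcPRX64	Aco028441	LG20	8837469	8839195	303	2	100	11.33	9.96
AcPRX65	Aco009344	LG22	7804594	7809328	948	4	315	33.75	6.06
AcPRX66	Aco017479	LG22	1177709	1189266	3174	9	1057	118.18	5.84
AcPRX67	Aco007303	LG23	3248931	3253068	981	4	326	34.91	6.1
AcPRX68	Aco012993	LG25	1550545	1551925	975	4	324	35.04	6.07
AcPRX69	Aco012994	LG25	1544211	1545775	984	4	327	35.19	7.54
AcPRX70	Aco030748	scaffold_1315	7476	13988	1059	4	352	37.48	4.73
AcPRX71	Aco028733	scaffold_1328	5042	7342	981	4	326	35.37	4.87
AcPRX72	Aco029135	scaffold_1464	25017	29639	1227	3	408	43.69	6.23
AcPRX73	Aco029860	scaffold_1666	5369	16413	1758	8	585	63.71	8.93
AcPRX74	Aco027813	scaffold_1838	5808	8224	999	4	332	35.12	4.61
AcPRX75	Aco031666	scaffold_2216	6898	8468	966	3	321	34.55	7.07
AcPRX76	Aco029389	scaffold_2281	5013	7429	999	4	332	35.12	4.61
AcPRX77	Aco031596	scaffold_2950	101	3231	693	3	230	25.96	9.4
AcPRX78	Aco025498	scaffold_691	13170	16131	1056	3	351	38.0	10.28
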