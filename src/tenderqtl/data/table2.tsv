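bta	start	end	tag_snp	tag_pos	n_snps	n_top500	in_qtldb	breeds	rank_angus	rank_hereford	rank_charolais	rank_limousin	rank_simmental	rank_all
1	27034490	29073969	rs42409195	28111487	30	2	0	C,L,S	7433	6333	37	189	19	335
1	155725361	156105357	rs41600022	155725361	8	1	0	H,L,S	2242	43	967	429	267	423
3	306322	1267869	ss86301348	1267869	17	1	0	A,H,C	154	134	222	6584	3319	210
4	62189085	62766260	rs43403458	62685650	16	2	0	H,C,S	2695	244	292	1679	176	60
5	4501932	5240327	ss86306901	5012505	15	1	1	A,H,S	90	422	8827	3688	453	458
5	21876606	23103768	rs29014779	21876606	19	1	0	C,L,S	846	3002	51	441	181	444
5	99077991	101271357	rs41654473	101271357	24	1	0	C,L,S	1105	1269	83	280	270	319
6	20730690	22576164	rs42756258	21884446	36	2	0	A,C,L,S	10	2467	191	304	78	190
6	102116041	104245701	ss117968229	103281884	44	3	0	A,L,S	214	625	1463	94	48	273
7	55116289	57554684	rs29012174	55116289	36	1	0	A,H,L,S	65	132	727	105	262	47
7	73155944	74367220	ss86318554	74367220	28	1	0	A,H,C,L	358	102	470	144	3570	288
7	77854696	83621039	rs43527386	80731488	89	3	0	H,C,L,S	1478	94	420	219	424	71
7	97861341	98820742	rs41255587	98579574	19	8	1	A,H,C,L,S	237	1	14	37	308	10
7	106927241	108205624	rs43531510	106927241	24	2	0	H,C,S	8668	163	49	972	306	98
8	3830280	4955143	rs41618019	4955143	19	1	0	A,H,S	137	57	534	9307	189	296
8	43890714	46946557	rs42312419	43890714	48	1	0	H,C,L,S	3561	208	16	410	126	31
8	65338177	69622989	ss117969253	68894735	68	4	0	A,H,C,L,S	156	85	198	240	90	29
8	97684074	98861495	ss86319219	98746331	16	1	0	A,H,C,L	31	181	238	141	4390	184
8	112287843	113301368	ss86338099	112824694	28	2	0	A,C,L,S	76	1615	123	369	235	330
9	36960364	40088647	rs41623216	38252618	41	2	0	H,L,S	1224	410	1033	126	151	188
10	6871209	8514821	ss86317616	7830003	26	1	0	A,L,S	299	2813	3578	238	99	338
10	15413589	16985300	ss86317957	16326848	34	1	0	A,H,L,S	383	128	4565	486	451	113
10	29278086	31692125	ss86305679	29278086	29	1	0	A,H,L,S	162	184	896	449	293	161
10	38799891	40135969	rs42412333	39278374	18	4	0	A,H,S	222	120	4536	1974	336	211
10	96842358	98541920	rs41590854	97410796	26	1	0	A,H,L	239	415	777	113	764	262
10	102286251	103234411	rs41596899	102308122	25	3	0	H,C,L,S	3577	393	184	103	103	160
11	1214856	1963074	ss86324631	1214865	21	1	0	H,C,L,S	10476	235	469	173	107	124
11	31734782	33348373	rs41606137	32224661	26	3	0	A,L,S	288	1652	1054	336	168	241
12	35454037	36764448	ss117970656	35581416	20	3	0	H,C,S	3094	50	489	4969	211	149
12	50715278	52618243	rs43699567	52573538	40	1	0	A,H,C,L,S	416	288	385	352	27	498
13	3723531	5128166	rs42862024	4308889	22	2	0	A,H,S	107	381	3033	2879	341	305
13	29072163	33201457	rs29011158	31826409	64	2	0	A,H,C,L,S	315	242	31	36	4	151
13	66080035	69702161	rs41631563	66080035	72	14	0	A,H,C,S	471	8	61	787	142	97
13	73369210	73746516	ss86338902	73746516	9	1	0	A,H,S	344	127	594	2950	130	283
13	75018157	76078033	ss86289318	76042839	24	2	0	A,C,S	41	773	65	1767	110	43
13	80848032	81665695	rs42630433	81029787	21	3	0	A,H,C,L	386	48	69	41	5004	75
14	18732660	20347849	rs41633333	18756025	32	5	0	A,H,C	293	414	87	573	2160	76
14	47926524	48572837	ss86299784	48184967	13	1	0	C,L,S	2191	871	301	195	109	302
14	62549674	63827753	ss86297726	63213438	24	1	0	A,H,C,L	352	301	97	275	1445	166
15	31599942	33310389	ss86291817	32861621	32	4	0	A,H,L	311	31	1527	243	553	162
15	34682617	36817688	rs41757680	35661186	40	1	1	A,H,C,L,S	99	21	53	32	468	354
15	48688111	50222093	rs41582705	48936679	10	1	0	C,L,S	4718	5799	172	162	124	119
15	62309986	63517557	rs41621125	63253454	20	1	0	H,C,L	9112	77	109	444	3538	74
15	64876840	66717899	ss86314348	64876840	15	1	0	H,C,L,S	1137	42	20	84	92	32
15	81655317	82875229	ss86296417	82768398	25	1	0	H,C,L	626	152	80	122	1842	178
16	11797915	13358683	rs41623175	12130589	23	2	0	A,H,C,L	18	18	4	272	1145	44
16	17070345	19313882	ss86290236	18059649	19	1	0	A,C,L,S	334	2017	256	381	96	353
16	22147468	23830920	ss86329907	22406467	17	1	0	A,H,C	401	88	354	1452	1920	216
16	25000153	28384914	ss86291490	27629566	39	4	0	H,C,L,S	1089	166	19	234	37	148
16	71968734	72962506	rs41824081	72165897	20	2	0	H,C,L	6937	265	467	55	2353	25
17	34429947	37201424	rs41626299	34429947	25	1	0	H,C,L,S	1866	131	391	420	479	195
17	63049154	64637527	ss86317522	63049154	29	1	0	A,C,L,S	205	1220	347	454	391	278
17	73315120	74393620	ss86339946	73315120	27	1	0	A,C,S	166	551	361	5105	22	403
18	4723911	6440525	ss86336538	4723911	32	1	0	A,L,S	333	580	3125	151	251	83
18	55028139	55621823	ss86310123	55590144	10	1	0	A,H,S	363	418	5999	2353	28	489
20	15870897	17710059	rs41933103	17175071	35	3	0	H,C,L	1892	44	52	320	1009	36
20	64002006	66587451	ss86335963	66105424	51	2	1	A,C,L,S	142	831	273	295	261	206
21	33764430	34810865	rs29015146	34165847	19	1	0	A,H,S	378	397	2032	924	322	434
21	40955783	43096903	rs42503056	40955783	30	1	0	A,H,S	116	350	4015	2961	113	85
21	59665710	61121046	rs41585245	61121046	22	3	0	A,C,L	458	703	211	205	1790	67
21	68152356	68965986	ss86312849	68846429	17	4	0	H,C,L	2122	108	209	83	1796	33
23	48537019	49094579	rs41617911	48856081	16	1	0	A,C,L	89	2461	332	448	2831	329
25	1160378	2105645	ss117973580	1919606	21	2	0	A,L,S	215	1633	2777	387	478	116
25	14683151	15752362	ss86336453	15752362	23	2	0	A,C,L,S	96	1940	306	60	145	132
25	19762712	22728704	rs41572366	21655452	47	2	0	A,H,C,L,S	97	63	495	3	258	102
25	27545745	30572524	ss86283327	29485851	48	2	1	A,H,C,L,S	57	499	99	102	68	49
26	12580311	14127433	ss86273489	13293856	27	1	0	A,H,S	27	107	4581	641	461	144
26	17058843	18288540	ss86287439	18288540	25	2	0	A,H,L,S	243	404	512	93	212	138
26	29698221	31348288	rs41646897	30903998	37	1	0	A,H,C,S	420	76	317	897	183	63
26	41183634	43312255	ss86282954	42274097	37	2	0	H,L,S	3947	23	701	256	445	388
27	3343936	6388642	rs29024621	3909806	24	1	0	A,H,L,S	275	80	2437	412	201	401
27	19195734	21993669	rs42118878	19195734	39	4	0	H,L,S	2323	323	538	192	42	35
27	34978041	36054950	ss86310277	35372600	21	1	0	A,H,C,S	304	425	149	1423	222	364
28	4837387	5876902	rs41612729	5052476	24	3	0	H,C,L,S	1466	317	438	117	233	280
28	31700004	34066383	ss86337100	33570352	33	1	0	A,H,L,S	39	138	3800	70	7	19
28	37398488	38314983	rs29013966	37514643	20	1	0	H,C,S	624	320	110	916	450	84
28	43815607	44961253	ss86283362	44694578	25	1	0	A,C,S	153	834	121	696	84	389
29	34618653	36573929	rs29022154	35387115	35	2	0	A,C,L,S	120	2258	276	35	87	129
29	44042363	44087629	rs42192103	44070713	30	18	1	A,H,C,L,S	1	4	1	30	1	1
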