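chr1	32166	32249	B10:tandem_contraction	231	.	tandem_contraction	sequence	0
chr1	250196	251804	B10:deletion	1608	.	deletion	sequence	0
chr1	255393	256179	B10:deletion	786	.	deletion	sequence	0
chr1	278016	278016	B10:insertion	5158	.	insertion	sequence	0
chr1	346534	346636	B10:deletion	102	.	deletion	sequence	0
chr1	447370	447750	B10:deletion	380	.	deletion	sequence	0
chr1	455392	455637	B10:deletion	245	.	deletion	sequence	0
chr1	463710	463710	B10:insertion	9816	.	insertion	sequence	0
chr1	503622	503950	B10:deletion	328	.	deletion	sequence	0
chr1	580903	589555	B10:deletion	8652	.	deletion	sequence	0
chr1	643664	650361	B10:deletion	6697	.	deletion	sequence	0
chr1	705161	705311	B10:tandem_contraction	240	.	tandem_contraction	sequence	0
chr1	725519	725900	B10:repeat_expansion	140	.	repeat_expansion	sequence	0
chr1	763691	764491	B10:repeat_expansion	680	.	repeat_expansion	sequence	0
chr1	773593	773593	B10:insertion	415	.	insertion	sequence	0
chr1	784711	785065	B10:tandem_expansion	594	.	tandem_expansion	sequence	0
chr1	792452	792984	B10:tandem_expansion	728	.	tandem_expansion	sequence	0
chr1	812420	812420	B10:insertion	1475	.	insertion	sequence	0
chr1	870440	870440	B10:insertion	726	.	insertion	sequence	0
chr1	977124	977124	B10:insertion	88	.	insertion	sequence	0
chr1	987842	987842	B10:insertion	65	.	insertion	sequence	0
chr1	1057352	1057578	B10:deletion	226	.	deletion	sequence	0
chr1	1151096	1151585	B10:deletion	489	.	deletion	sequence	0
chr1	1223331	1223706	B10:repeat_expansion	132	.	repeat_expansion	sequence	0
chr1	1276619	1276889	B10:repeat_expansion	216	.	repeat_expansion	sequence	0
chr1	1428918	1429154	B10:deletion	236	.	deletion	sequence	0
chr1	1438677	1438774	B10:deletion	97	.	deletion	sequence	0
chr1	1481746	1482452	B10:deletion	706	.	deletion	sequence	0
chr1	1495725	1496391	B10:tandem_expansion	740	.	tandem_expansion	sequence	0
chr1	1513201	1513201	B10:insertion	2802	.	insertion	sequence	0
chr1	1605077	1605597	B10:tandem_expansion	702	.	tandem_expansion	sequence	0
chr1	1626337	1626676	B10:repeat_expansion	104	.	repeat_expansion	sequence	0
chr1	1693733	1694455	B10:repeat_expansion	360	.	repeat_expansion	sequence	0
chr1	1720848	1721086	B10:repeat_contraction	51	.	repeat_contraction	sequence	0
chr1	1764340	1764700	B10:tandem_expansion	504	.	tandem_expansion	sequence	0
chr1	1796037	1796557	B10:repeat_expansion	416	.	repeat_expansion	sequence	0
chr1	1943924	1943924	B10:insertion	3048	.	insertion	sequence	0
chr1	1952744	1953504	B10:repeat_expansion	680	.	repeat_expansion	sequence	0
chr1	2014325	2014773	B10:repeat_contraction	112	.	repeat_contraction	sequence	0
chr1	2032441	2032491	B10:deletion	50	.	deletion	sequence	0
chr1	2202585	2202886	B10:repeat_expansion	260	.	repeat_expansion	sequence	0
chr1	2272841	2272996	B10:deletion	155	.	deletion	sequence	0
chr1	2280136	2280319	B10:tandem_contraction	345	.	tandem_contraction	sequence	0
chr1	2286509	2288642	B10:deletion	2133	.	deletion	sequence	0
chr1	2349856	2355122	B10:deletion	5266	.	deletion	sequence	0
chr1	2379971	2379971	B10:insertion	662	.	insertion	sequence	0
chr1	2398475	2403763	B10:deletion	5288	.	deletion	sequence	0
chr1	2430838	2431210	B10:repeat_expansion	124	.	repeat_expansion	sequence	0
chr1	2448775	2448775	B10:insertion	75	.	insertion	sequence	0
chr1	2477280	2477355	B10:tandem_contraction	228	.	tandem_contraction	sequence	0
chr1	2524653	2524653	B10:insertion	1028	.	insertion	sequence	0
chr1	2550864	2551392	B10:deletion	528	.	deletion	sequence	0
chr2	43159	43835	B10:tandem_expansion	1377	.	tandem_expansion	sequence	0
chr2	72125	72125	B10:insertion	235	.	insertion	sequence	0
chr2	176618	176998	B10:repeat_expansion	80	.	repeat_expansion	sequence	0
chr2	185615	190757	B10:deletion	5142	.	deletion	sequence	0
chr2	218605	218605	B10:insertion	144	.	insertion	sequence	0
chr2	247015	247015	B10:insertion	80	.	insertion	sequence	0
chr2	310669	310779	B10:deletion	110	.	deletion	sequence	0
chr2	328491	328553	B10:deletion	62	.	deletion	sequence	0
chr2	365127	365127	B10:insertion	203	.	insertion	sequence	0
chr2	514454	515100	B10:tandem_contraction	748	.	tandem_contraction	sequence	0
chr2	570025	570379	B10:repeat_expansion	64	.	repeat_expansion	sequence	0
chr2	576818	576961	B10:deletion	143	.	deletion	sequence	0
chr2	583124	583463	B10:repeat_expansion	156	.	repeat_expansion	sequence	0
chr2	685568	685760	B10:tandem_contraction	264	.	tandem_contraction	sequence	0
chr2	690313	690593	B10:repeat_contraction	200	.	repeat_contraction	sequence	0
chr2	748199	748282	B10:deletion	83	.	deletion	sequence	0
chr2	766326	766728	B10:tandem_expansion	735	.	tandem_expansion	sequence	0
chr2	773495	773587	B10:deletion	92	.	deletion	sequence	0
chr2	782856	783671	B10:deletion	815	.	deletion	sequence	0
chr2	798023	798471	B10:repeat_contraction	64	.	repeat_contraction	sequence	0
chr2	806927	807301	B10:repeat_expansion	102	.	repeat_expansion	sequence	0
chr2	814476	814963	B10:deletion	487	.	deletion	sequence	0
chr2	829288	834629	B10:deletion	5341	.	deletion	sequence	0
chr2	930897	931398	B10:repeat_expansion	100	.	repeat_expansion	sequence	0
chr2	971036	971351	B10:tandem_contraction	490	.	tandem_contraction	sequence	0
chr2	1015652	1016426	B10:deletion	774	.	deletion	sequence	0
chr2	1022325	1025011	B10:deletion	2686	.	deletion	sequence	0
chr2	1093071	1095024	B10:deletion	1953	.	deletion	sequence	0
chr2	1108751	1110571	B10:deletion	1820	.	deletion	sequence	0
chr2	1127352	1127352	B10:insertion	116	.	insertion	sequence	0
chr2	1138587	1146174	B10:deletion	7587	.	deletion	sequence	0
chr2	1157666	1158035	B10:tandem_expansion	576	.	tandem_expansion	sequence	0
chr2	1190180	1190180	B10:insertion	350	.	insertion	sequence	0
chr2	1216964	1216964	B10:insertion	592	.	insertion	sequence	0
chr2	1255790	1256293	B10:deletion	503	.	deletion	sequence	0
chr2	1287186	1287766	B10:repeat_expansion	480	.	repeat_expansion	sequence	0
chr2	1350053	1350266	B10:tandem_contraction	408	.	tandem_contraction	sequence	0
chr2	1364868	1367488	B10:deletion	2620	.	deletion	sequence	0
chr2	1387543	1390271	B10:deletion	2728	.	deletion	sequence	0
chr2	1395472	1395529	B10:tandem_contraction	152	.	tandem_contraction	sequence	0
chr2	1406154	1406154	B10:insertion	4619	.	insertion	sequence	0
chr2	1481663	1482123	B10:tandem_expansion	729	.	tandem_expansion	sequence	0
chr2	1584149	1584488	B10:deletion	339	.	deletion	sequence	0
chr2	1644371	1647630	B10:deletion	3259	.	deletion	sequence	0
chr2	1859443	1861599	B10:deletion	2156	.	deletion	sequence	0
chr2	1913099	1913099	B10:insertion	98	.	insertion	sequence	0
chr2	1950097	1950097	B10:insertion	653	.	insertion	sequence	0
chr2	2091187	2091349	B10:repeat_contraction	115	.	repeat_contraction	sequence	0
chr2	2099799	2100126	B10:repeat_contraction	100	.	repeat_contraction	sequence	0
chr2	2184129	2184129	B10:insertion	1134	.	insertion	sequence	0
chr2	2309256	2309256	B10:insertion	4045	.	insertion	sequence	0
chr2	2317286	2317286	B10:insertion	817	.	insertion	sequence	0
chr2	2420442	2420611	B10:repeat_contraction	126	.	repeat_contraction	sequence	0
chr2	2461361	2461361	B10:insertion	330	.	insertion	sequence	0
chr1	127626	146320	B10:inversion	18694	.	inversion	sequence	0
chr1	889928	908395	B10:inversion	18467	.	inversion	sequence	0
chr1	1018422	1033773	B10:inversion	15351	.	inversion	sequence	0
chr1	1162010	1188987	B10:inversion	26977	.	inversion	sequence	0
chr1	1296957	1316506	B10:inversion	19549	.	inversion	sequence	0
chr1	2121731	2147044	B10:inversion	25313	.	inversion	sequence	0
chr2	129672	146286	B10:inversion	16614	.	inversion	sequence	0
chr2	525245	546378	B10:inversion	21133	.	inversion	sequence	0
chr2	1702697	1718466	B10:inversion	15769	.	inversion	sequence	0
chr2	1817325	1844079	B10:inversion	26754	.	inversion	sequence	0
chr2	2378144	2398794	B10:inversion	20650	.	inversion	sequence	0
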