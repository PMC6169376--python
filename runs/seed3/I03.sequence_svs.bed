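chr1	32166	32249	I03:tandem_contraction	231	.	tandem_contraction	sequence	0
chr1	88992	89400	I03:repeat_contraction	68	.	repeat_contraction	sequence	0
chr1	92620	94421	I03:deletion	1801	.	deletion	sequence	0
chr1	213482	213482	I03:insertion	5634	.	insertion	sequence	0
chr1	247012	247012	I03:insertion	1897	.	insertion	sequence	0
chr1	255393	256179	I03:deletion	786	.	deletion	sequence	0
chr1	278016	278016	I03:insertion	5158	.	insertion	sequence	0
chr1	447370	447750	I03:deletion	380	.	deletion	sequence	0
chr1	463710	463710	I03:insertion	9816	.	insertion	sequence	0
chr1	503622	503950	I03:deletion	328	.	deletion	sequence	0
chr1	638132	638762	I03:deletion	630	.	deletion	sequence	0
chr1	643664	650361	I03:deletion	6697	.	deletion	sequence	0
chr1	725519	725900	I03:repeat_expansion	140	.	repeat_expansion	sequence	0
chr1	730541	730637	I03:tandem_contraction	216	.	tandem_contraction	sequence	0
chr1	745414	745889	I03:repeat_expansion	100	.	repeat_expansion	sequence	0
chr1	763691	764491	I03:repeat_expansion	680	.	repeat_expansion	sequence	0
chr1	773593	773593	I03:insertion	415	.	insertion	sequence	0
chr1	792452	792984	I03:tandem_expansion	728	.	tandem_expansion	sequence	0
chr1	870440	870440	I03:insertion	726	.	insertion	sequence	0
chr1	987842	987842	I03:insertion	65	.	insertion	sequence	0
chr1	1151096	1151585	I03:deletion	489	.	deletion	sequence	0
chr1	1223331	1223706	I03:repeat_expansion	132	.	repeat_expansion	sequence	0
chr1	1231866	1232370	I03:tandem_expansion	900	.	tandem_expansion	sequence	0
chr1	1276619	1276889	I03:repeat_expansion	216	.	repeat_expansion	sequence	0
chr1	1428918	1429154	I03:deletion	236	.	deletion	sequence	0
chr1	1466577	1467136	I03:repeat_expansion	93	.	repeat_expansion	sequence	0
chr1	1495725	1496391	I03:tandem_expansion	740	.	tandem_expansion	sequence	0
chr1	1605077	1605597	I03:tandem_expansion	702	.	tandem_expansion	sequence	0
chr1	1626337	1626676	I03:repeat_expansion	104	.	repeat_expansion	sequence	0
chr1	1720848	1721086	I03:repeat_contraction	51	.	repeat_contraction	sequence	0
chr1	1764340	1764700	I03:tandem_expansion	504	.	tandem_expansion	sequence	0
chr1	1796037	1796557	I03:repeat_expansion	416	.	repeat_expansion	sequence	0
chr1	1943924	1943924	I03:insertion	3048	.	insertion	sequence	0
chr1	1952744	1953504	I03:repeat_expansion	680	.	repeat_expansion	sequence	0
chr1	2032441	2032491	I03:deletion	50	.	deletion	sequence	0
chr1	2080043	2082356	I03:deletion	2313	.	deletion	sequence	0
chr1	2172888	2177801	I03:deletion	4913	.	deletion	sequence	0
chr1	2202585	2202886	I03:repeat_expansion	260	.	repeat_expansion	sequence	0
chr1	2272841	2272996	I03:deletion	155	.	deletion	sequence	0
chr1	2280136	2280319	I03:tandem_contraction	345	.	tandem_contraction	sequence	0
chr1	2379971	2379971	I03:insertion	662	.	insertion	sequence	0
chr1	2398475	2403763	I03:deletion	5288	.	deletion	sequence	0
chr1	2448775	2448775	I03:insertion	75	.	insertion	sequence	0
chr1	2524653	2524653	I03:insertion	1028	.	insertion	sequence	0
chr1	2550864	2551392	I03:deletion	528	.	deletion	sequence	0
chr2	64228	64228	I03:insertion	87	.	insertion	sequence	0
chr2	72125	72125	I03:insertion	235	.	insertion	sequence	0
chr2	176618	176998	I03:repeat_expansion	80	.	repeat_expansion	sequence	0
chr2	218605	218605	I03:insertion	144	.	insertion	sequence	0
chr2	247015	247015	I03:insertion	80	.	insertion	sequence	0
chr2	278637	279340	I03:tandem_expansion	858	.	tandem_expansion	sequence	0
chr2	310669	310779	I03:deletion	110	.	deletion	sequence	0
chr2	351580	351989	I03:deletion	409	.	deletion	sequence	0
chr2	506364	507384	I03:deletion	1020	.	deletion	sequence	0
chr2	514454	515100	I03:tandem_contraction	748	.	tandem_contraction	sequence	0
chr2	570025	570379	I03:repeat_expansion	64	.	repeat_expansion	sequence	0
chr2	748199	748282	I03:deletion	83	.	deletion	sequence	0
chr2	766326	766728	I03:tandem_expansion	735	.	tandem_expansion	sequence	0
chr2	773495	773587	I03:deletion	92	.	deletion	sequence	0
chr2	782856	783671	I03:deletion	815	.	deletion	sequence	0
chr2	798023	798471	I03:repeat_contraction	64	.	repeat_contraction	sequence	0
chr2	806927	807301	I03:repeat_expansion	102	.	repeat_expansion	sequence	0
chr2	829288	834629	I03:deletion	5341	.	deletion	sequence	0
chr2	930897	931398	I03:repeat_expansion	100	.	repeat_expansion	sequence	0
chr2	971036	971351	I03:tandem_contraction	490	.	tandem_contraction	sequence	0
chr2	1007986	1008049	I03:deletion	63	.	deletion	sequence	0
chr2	1015652	1016426	I03:deletion	774	.	deletion	sequence	0
chr2	1078592	1078592	I03:insertion	97	.	insertion	sequence	0
chr2	1089660	1090320	I03:tandem_expansion	1155	.	tandem_expansion	sequence	0
chr2	1093071	1095024	I03:deletion	1953	.	deletion	sequence	0
chr2	1108751	1110571	I03:deletion	1820	.	deletion	sequence	0
chr2	1157666	1158035	I03:tandem_expansion	576	.	tandem_expansion	sequence	0
chr2	1184772	1184772	I03:insertion	669	.	insertion	sequence	0
chr2	1193929	1193929	I03:insertion	1116	.	insertion	sequence	0
chr2	1287186	1287766	I03:repeat_expansion	480	.	repeat_expansion	sequence	0
chr2	1296587	1296686	I03:repeat_contraction	132	.	repeat_contraction	sequence	0
chr2	1350053	1350266	I03:tandem_contraction	408	.	tandem_contraction	sequence	0
chr2	1364868	1367488	I03:deletion	2620	.	deletion	sequence	0
chr2	1387543	1390271	I03:deletion	2728	.	deletion	sequence	0
chr2	1484462	1484556	I03:deletion	94	.	deletion	sequence	0
chr2	1584149	1584488	I03:deletion	339	.	deletion	sequence	0
chr2	1644371	1647630	I03:deletion	3259	.	deletion	sequence	0
chr2	1801335	1801521	I03:deletion	186	.	deletion	sequence	0
chr2	1859443	1861599	I03:deletion	2156	.	deletion	sequence	0
chr2	1913099	1913099	I03:insertion	98	.	insertion	sequence	0
chr2	1950097	1950097	I03:insertion	653	.	insertion	sequence	0
chr2	2069903	2069969	I03:tandem_contraction	242	.	tandem_contraction	sequence	0
chr2	2099799	2100126	I03:repeat_contraction	100	.	repeat_contraction	sequence	0
chr2	2184129	2184129	I03:insertion	1134	.	insertion	sequence	0
chr2	2217461	2217461	I03:insertion	324	.	insertion	sequence	0
chr2	2309256	2309256	I03:insertion	4045	.	insertion	sequence	0
chr2	2505450	2505720	I03:tandem_expansion	351	.	tandem_expansion	sequence	0
chr2	2529018	2531845	I03:deletion	2827	.	deletion	sequence	0
chr1	127626	146320	I03:inversion	18694	.	inversion	sequence	0
chr1	889928	908395	I03:inversion	18467	.	inversion	sequence	0
chr1	1018422	1033773	I03:inversion	15351	.	inversion	sequence	0
chr1	1162010	1188987	I03:inversion	26977	.	inversion	sequence	0
chr1	1296957	1316506	I03:inversion	19549	.	inversion	sequence	0
chr1	1877225	1894290	I03:inversion	17065	.	inversion	sequence	0
chr1	2121731	2147044	I03:inversion	25313	.	inversion	sequence	0
chr2	129672	146286	I03:inversion	16614	.	inversion	sequence	0
chr2	1702697	1718466	I03:inversion	15769	.	inversion	sequence	0
chr2	1817325	1844079	I03:inversion	26754	.	inversion	sequence	0
chr2	2378144	2398794	I03:inversion	20650	.	inversion	sequence	0
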