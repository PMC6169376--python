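chr1	127050	128031	ZH26:insertion	2129	.	insertion	optical	0
chr1	130231	130885	ZH26:insertion	5492	.	insertion	optical	0
chr1	135427	152891	ZH26:deletion	14608	.	deletion	optical	0
chr1	273542	279369	ZH26:insertion	5172	.	insertion	optical	0
chr1	291877	295833	ZH26:insertion	2774	.	insertion	optical	0
chr1	324314	332668	ZH26:deletion	4840	.	deletion	optical	0
chr1	401463	405588	ZH26:insertion	3884	.	insertion	optical	0
chr1	422486	423649	ZH26:deletion	1116	.	deletion	optical	0
chr1	538985	544485	ZH26:insertion	1447	.	insertion	optical	0
chr1	643298	650979	ZH26:deletion	6710	.	deletion	optical	0
chr1	718503	723335	ZH26:insertion	1092	.	insertion	optical	0
chr1	882225	884051	ZH26:insertion	2222	.	insertion	optical	0
chr1	1050224	1054867	ZH26:insertion	5235	.	insertion	optical	0
chr1	1126910	1128837	ZH26:insertion	1442	.	insertion	optical	0
chr1	1828759	1834189	ZH26:insertion	1297	.	insertion	optical	0
chr1	1913997	1920867	ZH26:insertion	2736	.	insertion	optical	0
chr1	1989161	1994064	ZH26:insertion	7871	.	insertion	optical	0
chr1	2486114	2496905	ZH26:deletion	6592	.	deletion	optical	0
chr1	2496982	2498960	ZH26:deletion	1726	.	deletion	optical	0
chr1	2500428	2500678	ZH26:insertion	1737	.	insertion	optical	0
chr1	2500826	2501666	ZH26:insertion	6551	.	insertion	optical	0
chr1	2523862	2525632	ZH26:insertion	1036	.	insertion	optical	0
chr2	19968	23023	ZH26:insertion	9434	.	insertion	optical	0
chr2	32152	39665	ZH26:insertion	3365	.	insertion	optical	0
chr2	101786	112061	ZH26:deletion	7796	.	deletion	optical	0
chr2	225016	228728	ZH26:insertion	6087	.	insertion	optical	0
chr2	237367	246922	ZH26:deletion	6589	.	deletion	optical	0
chr2	333441	336521	ZH26:deletion	1236	.	deletion	optical	0
chr2	647688	663207	ZH26:deletion	8951	.	deletion	optical	0
chr2	726069	736606	ZH26:insertion	1234	.	insertion	optical	0
chr2	828646	839186	ZH26:deletion	5349	.	deletion	optical	0
chr2	847818	858789	ZH26:deletion	1691	.	deletion	optical	0
chr2	936150	942478	ZH26:insertion	1347	.	insertion	optical	0
chr2	1198792	1209034	ZH26:deletion	2156	.	deletion	optical	0
chr2	1380533	1390304	ZH26:deletion	2727	.	deletion	optical	0
chr2	1492149	1495244	ZH26:deletion	2816	.	deletion	optical	0
chr2	1636912	1654233	ZH26:deletion	3688	.	deletion	optical	0
chr2	1748416	1777145	ZH26:deletion	8189	.	deletion	optical	0
chr2	1810253	1816690	ZH26:insertion	6473	.	insertion	optical	0
chr2	1817063	1822522	ZH26:deletion	1903	.	deletion	optical	0
chr2	1833447	1845547	ZH26:deletion	5428	.	deletion	optical	0
chr2	1858212	1865577	ZH26:deletion	2129	.	deletion	optical	0
chr2	2036427	2037685	ZH26:insertion	2567	.	insertion	optical	0
chr2	2083940	2086751	ZH26:insertion	4708	.	insertion	optical	0
chr2	2195781	2197081	ZH26:insertion	1840	.	insertion	optical	0
chr2	2204373	2205761	ZH26:insertion	1519	.	insertion	optical	0
chr2	2303627	2314745	ZH26:insertion	2147	.	insertion	optical	0
chr2	2410640	2416451	ZH26:insertion	2726	.	insertion	optical	0
chr2	2457317	2458734	ZH26:insertion	4029	.	insertion	optical	0
chr2	2482951	2490272	ZH26:deletion	2564	.	deletion	optical	0
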