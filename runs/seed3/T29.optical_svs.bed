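chr1	168926	176797	T29:insertion	3432	.	insertion	optical	0
chr1	273542	281325	T29:insertion	5182	.	insertion	optical	0
chr1	291877	302187	T29:insertion	1313	.	insertion	optical	0
chr1	357750	358165	T29:insertion	1418	.	insertion	optical	0
chr1	369429	382115	T29:deletion	9170	.	deletion	optical	0
chr1	422486	423649	T29:deletion	1116	.	deletion	optical	0
chr1	619021	621884	T29:deletion	1677	.	deletion	optical	0
chr1	643298	651837	T29:deletion	6700	.	deletion	optical	0
chr1	667976	675121	T29:insertion	1602	.	insertion	optical	0
chr1	853904	857086	T29:insertion	2832	.	insertion	optical	0
chr1	869667	881411	T29:insertion	1357	.	insertion	optical	0
chr1	1156791	1167532	T29:insertion	15780	.	insertion	optical	0
chr1	1167638	1195287	T29:deletion	16080	.	deletion	optical	0
chr1	1377325	1388356	T29:deletion	3823	.	deletion	optical	0
chr1	1423527	1428034	T29:insertion	3373	.	insertion	optical	0
chr1	1428513	1436837	T29:insertion	1659	.	insertion	optical	0
chr1	1442370	1447422	T29:deletion	3924	.	deletion	optical	0
chr1	1549426	1552006	T29:insertion	1096	.	insertion	optical	0
chr1	1633093	1642128	T29:deletion	5545	.	deletion	optical	0
chr1	1913997	1917254	T29:insertion	1770	.	insertion	optical	0
chr1	1998888	2001421	T29:insertion	1195	.	insertion	optical	0
chr1	2004635	2017903	T29:insertion	1142	.	insertion	optical	0
chr1	2519530	2525632	T29:insertion	1557	.	insertion	optical	0
chr1	2530684	2549017	T29:insertion	7750	.	insertion	optical	0
chr2	19968	23023	T29:insertion	9490	.	insertion	optical	0
chr2	80402	91974	T29:deletion	9216	.	deletion	optical	0
chr2	225016	228728	T29:insertion	6128	.	insertion	optical	0
chr2	726069	734078	T29:insertion	1203	.	insertion	optical	0
chr2	828646	839186	T29:deletion	5381	.	deletion	optical	0
chr2	846307	855634	T29:deletion	2330	.	deletion	optical	0
chr2	936150	942478	T29:insertion	1414	.	insertion	optical	0
chr2	1048191	1058541	T29:deletion	4703	.	deletion	optical	0
chr2	1381165	1390304	T29:deletion	2807	.	deletion	optical	0
chr2	1643520	1647842	T29:deletion	3255	.	deletion	optical	0
chr2	1858212	1865577	T29:deletion	2132	.	deletion	optical	0
chr2	1867857	1874997	T29:deletion	5001	.	deletion	optical	0
chr2	2012295	2015741	T29:insertion	5145	.	insertion	optical	0
chr2	2144845	2149392	T29:insertion	1378	.	insertion	optical	0
chr2	2246468	2251729	T29:insertion	5859	.	insertion	optical	0
chr2	2259155	2267343	T29:deletion	1947	.	deletion	optical	0
chr2	2303627	2310711	T29:insertion	2095	.	insertion	optical	0
chr2	2333605	2337005	T29:insertion	9711	.	insertion	optical	0
chr2	2457317	2458734	T29:insertion	4038	.	insertion	optical	0
chr2	2482951	2490272	T29:deletion	2708	.	deletion	optical	0
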