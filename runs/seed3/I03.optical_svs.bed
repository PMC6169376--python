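chr1	92372	97219	I03:deletion	1795	.	deletion	optical	0
chr1	213192	214875	I03:insertion	5634	.	insertion	optical	0
chr1	246575	248686	I03:insertion	1915	.	insertion	optical	0
chr1	273542	279369	I03:insertion	5147	.	insertion	optical	0
chr1	463224	466207	I03:insertion	9813	.	insertion	optical	0
chr1	643298	650979	I03:deletion	6697	.	deletion	optical	0
chr1	1021883	1022207	I03:insertion	4619	.	insertion	optical	0
chr1	1025273	1030205	I03:deletion	4606	.	deletion	optical	0
chr1	1156791	1186841	I03:deletion	23303	.	deletion	optical	0
chr1	1190166	1195287	I03:insertion	23253	.	insertion	optical	0
chr1	1942719	1953990	I03:insertion	3670	.	insertion	optical	0
chr1	2076815	2086980	I03:deletion	2328	.	deletion	optical	0
chr1	2169056	2182327	I03:deletion	4860	.	deletion	optical	0
chr1	2397417	2405117	I03:deletion	5290	.	deletion	optical	0
chr1	2523862	2525632	I03:insertion	1033	.	insertion	optical	0
chr2	504745	507916	I03:deletion	1019	.	deletion	optical	0
chr2	828646	839186	I03:deletion	5362	.	deletion	optical	0
chr2	1089332	1092120	I03:insertion	1167	.	insertion	optical	0
chr2	1092611	1097005	I03:deletion	1947	.	deletion	optical	0
chr2	1106302	1110763	I03:deletion	1822	.	deletion	optical	0
chr2	1193882	1196308	I03:insertion	1104	.	insertion	optical	0
chr2	1364815	1370249	I03:deletion	2626	.	deletion	optical	0
chr2	1380533	1390304	I03:deletion	2722	.	deletion	optical	0
chr2	1643520	1647842	I03:deletion	3263	.	deletion	optical	0
chr2	1858212	1865577	I03:deletion	2118	.	deletion	optical	0
chr2	2181809	2190318	I03:insertion	1153	.	insertion	optical	0
chr2	2303627	2310711	I03:insertion	4042	.	insertion	optical	0
chr2	2525993	2534682	I03:deletion	2837	.	deletion	optical	0
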