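chr1	248686	258845	B10:deletion	2397	.	deletion	optical	0
chr1	271571	279369	B10:insertion	5172	.	insertion	optical	0
chr1	462863	466207	B10:insertion	9752	.	insertion	optical	0
chr1	576783	592410	B10:deletion	8656	.	deletion	optical	0
chr1	643298	650979	B10:deletion	6704	.	deletion	optical	0
chr1	811235	814382	B10:insertion	1491	.	insertion	optical	0
chr1	1512905	1515488	B10:insertion	2808	.	insertion	optical	0
chr1	1942719	1953946	B10:insertion	3692	.	insertion	optical	0
chr1	2285012	2290228	B10:deletion	2123	.	deletion	optical	0
chr1	2347282	2356095	B10:deletion	5277	.	deletion	optical	0
chr1	2397417	2405117	B10:deletion	5294	.	deletion	optical	0
chr1	2523862	2525632	B10:insertion	1034	.	insertion	optical	0
chr2	39665	44616	B10:insertion	1399	.	insertion	optical	0
chr2	181625	193039	B10:deletion	5169	.	deletion	optical	0
chr2	828646	839186	B10:deletion	5336	.	deletion	optical	0
chr2	1009746	1025523	B10:deletion	3543	.	deletion	optical	0
chr2	1092611	1097005	B10:deletion	1958	.	deletion	optical	0
chr2	1106302	1110763	B10:deletion	1817	.	deletion	optical	0
chr2	1138133	1147215	B10:deletion	7593	.	deletion	optical	0
chr2	1364815	1370249	B10:deletion	2634	.	deletion	optical	0
chr2	1381165	1390304	B10:deletion	2657	.	deletion	optical	0
chr2	1404694	1407336	B10:insertion	4634	.	insertion	optical	0
chr2	1643520	1647842	B10:deletion	3267	.	deletion	optical	0
chr2	1700922	1713951	B10:deletion	7242	.	deletion	optical	0
chr2	1714471	1718575	B10:insertion	7288	.	insertion	optical	0
chr2	1817063	1822522	B10:insertion	5436	.	insertion	optical	0
chr2	1833447	1838602	B10:deletion	2599	.	deletion	optical	0
chr2	1840215	1844506	B10:deletion	2954	.	deletion	optical	0
chr2	1857833	1865577	B10:deletion	2140	.	deletion	optical	0
chr2	2181809	2190318	B10:insertion	1126	.	insertion	optical	0
chr2	2303627	2310711	B10:insertion	4092	.	insertion	optical	0
chr2	2386252	2386339	B10:insertion	2749	.	insertion	optical	0
chr2	2387628	2399542	B10:deletion	3003	.	deletion	optical	0
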