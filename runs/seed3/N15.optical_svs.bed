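chr1	193088	198339	N15:insertion	1053	.	insertion	optical	0
chr1	273542	279369	N15:insertion	5190	.	insertion	optical	0
chr1	291877	302187	N15:insertion	1232	.	insertion	optical	0
chr1	422486	423649	N15:deletion	1115	.	deletion	optical	0
chr1	643298	650979	N15:deletion	6694	.	deletion	optical	0
chr1	667305	675121	N15:insertion	1631	.	insertion	optical	0
chr1	831272	837315	N15:insertion	6711	.	insertion	optical	0
chr1	866904	881411	N15:insertion	1343	.	insertion	optical	0
chr1	952279	956956	N15:deletion	3873	.	deletion	optical	0
chr1	1046890	1049374	N15:insertion	1568	.	insertion	optical	0
chr1	1377325	1388356	N15:deletion	3766	.	deletion	optical	0
chr1	1549426	1552006	N15:insertion	1083	.	insertion	optical	0
chr1	1738358	1741268	N15:deletion	1935	.	deletion	optical	0
chr1	1913997	1917254	N15:insertion	1754	.	insertion	optical	0
chr1	1998888	2001421	N15:insertion	1178	.	insertion	optical	0
chr1	2004635	2012685	N15:insertion	1174	.	insertion	optical	0
chr1	2043335	2056269	N15:deletion	4805	.	deletion	optical	0
chr1	2523862	2525632	N15:insertion	1033	.	insertion	optical	0
chr1	2530684	2540705	N15:insertion	7771	.	insertion	optical	0
chr2	19968	23023	N15:insertion	9431	.	insertion	optical	0
chr2	225016	228728	N15:insertion	6114	.	insertion	optical	0
chr2	726069	734078	N15:insertion	1201	.	insertion	optical	0
chr2	828646	839257	N15:deletion	5443	.	deletion	optical	0
chr2	847818	855634	N15:deletion	2364	.	deletion	optical	0
chr2	936150	942478	N15:insertion	1350	.	insertion	optical	0
chr2	1048424	1057795	N15:deletion	4326	.	deletion	optical	0
chr2	1299159	1306268	N15:insertion	3695	.	insertion	optical	0
chr2	1381165	1390304	N15:deletion	3601	.	deletion	optical	0
chr2	1643520	1647842	N15:deletion	3257	.	deletion	optical	0
chr2	1671228	1681529	N15:deletion	5266	.	deletion	optical	0
chr2	1858212	1865577	N15:deletion	2147	.	deletion	optical	0
chr2	1867857	1874997	N15:deletion	5010	.	deletion	optical	0
chr2	2246468	2251729	N15:insertion	5895	.	insertion	optical	0
chr2	2259155	2267343	N15:deletion	1942	.	deletion	optical	0
chr2	2303627	2310711	N15:insertion	2042	.	insertion	optical	0
chr2	2333605	2337005	N15:insertion	9734	.	insertion	optical	0
chr2	2457317	2458734	N15:insertion	4003	.	insertion	optical	0
chr2	2479539	2490272	N15:deletion	2565	.	deletion	optical	0
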