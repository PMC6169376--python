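chr1	151451	158234	ZH26:deletion	6783	.	deletion	sequence	1
chr1	278016	278016	ZH26:insertion	5158	.	insertion	sequence	1
chr1	292872	292872	ZH26:insertion	2779	.	insertion	sequence	1
chr1	325298	330151	ZH26:deletion	4853	.	deletion	sequence	1
chr1	403024	403024	ZH26:insertion	3894	.	insertion	sequence	1
chr1	422496	423612	ZH26:deletion	1116	.	deletion	sequence	1
chr1	542462	542462	ZH26:insertion	1424	.	insertion	sequence	1
chr1	643664	650361	ZH26:deletion	6697	.	deletion	sequence	1
chr1	721645	721645	ZH26:insertion	1104	.	insertion	sequence	1
chr1	883391	883391	ZH26:insertion	2247	.	insertion	sequence	1
chr1	1053052	1053052	ZH26:insertion	5219	.	insertion	sequence	1
chr1	1128077	1128077	ZH26:insertion	1483	.	insertion	sequence	1
chr1	1829018	1829401	ZH26:tandem_expansion	418	.	tandem_expansion	sequence	1
chr1	1832828	1833694	ZH26:repeat_expansion	828	.	repeat_expansion	sequence	1
chr1	1914026	1914026	ZH26:insertion	1786	.	insertion	sequence	1
chr1	1919625	1920178	ZH26:tandem_expansion	928	.	tandem_expansion	sequence	1
chr1	1990259	1990259	ZH26:insertion	7820	.	insertion	sequence	1
chr1	2524653	2524653	ZH26:insertion	1028	.	insertion	sequence	1
chr2	21143	21143	ZH26:insertion	9435	.	insertion	sequence	1
chr2	38120	38120	ZH26:insertion	3298	.	insertion	sequence	1
chr2	103472	111273	ZH26:deletion	7801	.	deletion	sequence	1
chr2	225808	225808	ZH26:insertion	6116	.	insertion	sequence	1
chr2	237692	244288	ZH26:deletion	6596	.	deletion	sequence	1
chr2	333937	335173	ZH26:deletion	1236	.	deletion	sequence	1
chr2	652959	661872	ZH26:deletion	8913	.	deletion	sequence	1
chr2	730989	731675	ZH26:tandem_expansion	1216	.	tandem_expansion	sequence	1
chr2	829288	834629	ZH26:deletion	5341	.	deletion	sequence	1
chr2	850426	852761	ZH26:deletion	2335	.	deletion	sequence	1
chr2	940961	940961	ZH26:insertion	1376	.	insertion	sequence	1
chr2	1202343	1204536	ZH26:deletion	2193	.	deletion	sequence	1
chr2	1387543	1390271	ZH26:deletion	2728	.	deletion	sequence	1
chr2	1492226	1495042	ZH26:deletion	2816	.	deletion	sequence	1
chr2	1637910	1638398	ZH26:deletion	488	.	deletion	sequence	1
chr2	1644371	1647630	ZH26:deletion	3259	.	deletion	sequence	1
chr2	1657622	1657705	ZH26:deletion	83	.	deletion	sequence	1
chr2	1760339	1768304	ZH26:deletion	7965	.	deletion	sequence	1
chr2	1859443	1861599	ZH26:deletion	2156	.	deletion	sequence	1
chr2	2037503	2037503	ZH26:insertion	2577	.	insertion	sequence	1
chr2	2086673	2086673	ZH26:insertion	4695	.	insertion	sequence	1
chr2	2195804	2195804	ZH26:insertion	1869	.	insertion	sequence	1
chr2	2204209	2204209	ZH26:insertion	1884	.	insertion	sequence	1
chr2	2306217	2306217	ZH26:insertion	2063	.	insertion	sequence	1
chr2	2312946	2312946	ZH26:insertion	73	.	insertion	sequence	1
chr2	2413428	2413428	ZH26:insertion	2760	.	insertion	sequence	1
chr2	2458013	2458013	ZH26:insertion	4014	.	insertion	sequence	1
chr2	2484467	2486928	ZH26:deletion	2461	.	deletion	sequence	1
chr2	2490078	2490221	ZH26:deletion	143	.	deletion	sequence	1
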