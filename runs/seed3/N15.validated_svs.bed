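chr1	193278	194279	N15:tandem_expansion	1360	.	tandem_expansion	sequence	1
chr1	278016	278016	N15:insertion	5158	.	insertion	sequence	1
chr1	292872	292872	N15:insertion	2779	.	insertion	sequence	1
chr1	422496	423612	N15:deletion	1116	.	deletion	sequence	1
chr1	643664	650361	N15:deletion	6697	.	deletion	sequence	1
chr1	671328	671328	N15:insertion	1613	.	insertion	sequence	1
chr1	833661	833661	N15:insertion	6709	.	insertion	sequence	1
chr1	870440	870440	N15:insertion	726	.	insertion	sequence	1
chr1	879845	879845	N15:insertion	588	.	insertion	sequence	1
chr1	952668	956542	N15:deletion	3874	.	deletion	sequence	1
chr1	1048749	1048749	N15:insertion	1590	.	insertion	sequence	1
chr1	1382187	1385981	N15:deletion	3794	.	deletion	sequence	1
chr1	1549589	1550165	N15:tandem_expansion	1088	.	tandem_expansion	sequence	1
chr1	1738863	1740799	N15:deletion	1936	.	deletion	sequence	1
chr1	1914026	1914026	N15:insertion	1786	.	insertion	sequence	1
chr1	1999220	1999850	N15:tandem_expansion	1170	.	tandem_expansion	sequence	1
chr1	2010179	2010729	N15:tandem_expansion	1100	.	tandem_expansion	sequence	1
chr1	2050014	2054886	N15:deletion	4872	.	deletion	sequence	1
chr1	2524653	2524653	N15:insertion	1028	.	insertion	sequence	1
chr1	2535195	2535195	N15:insertion	7412	.	insertion	sequence	1
chr1	2539761	2540433	N15:repeat_expansion	308	.	repeat_expansion	sequence	1
chr2	21143	21143	N15:insertion	9435	.	insertion	sequence	1
chr2	225808	225808	N15:insertion	6116	.	insertion	sequence	1
chr2	730989	731675	N15:tandem_expansion	1216	.	tandem_expansion	sequence	1
chr2	829288	834629	N15:deletion	5341	.	deletion	sequence	1
chr2	850426	852761	N15:deletion	2335	.	deletion	sequence	1
chr2	940961	940961	N15:insertion	1376	.	insertion	sequence	1
chr2	1052240	1056623	N15:deletion	4383	.	deletion	sequence	1
chr2	1301210	1301210	N15:insertion	3698	.	insertion	sequence	1
chr2	1383220	1384065	N15:deletion	845	.	deletion	sequence	1
chr2	1387543	1390271	N15:deletion	2728	.	deletion	sequence	1
chr2	1644371	1647630	N15:deletion	3259	.	deletion	sequence	1
chr2	1675931	1681160	N15:deletion	5229	.	deletion	sequence	1
chr2	1859443	1861599	N15:deletion	2156	.	deletion	sequence	1
chr2	1868891	1873908	N15:deletion	5017	.	deletion	sequence	1
chr2	2247034	2247034	N15:insertion	5858	.	insertion	sequence	1
chr2	2263276	2265220	N15:deletion	1944	.	deletion	sequence	1
chr2	2306217	2306217	N15:insertion	2063	.	insertion	sequence	1
chr2	2312946	2312946	N15:insertion	73	.	insertion	sequence	1
chr2	2333943	2333943	N15:insertion	9756	.	insertion	sequence	1
chr2	2458013	2458013	N15:insertion	4014	.	insertion	sequence	1
chr2	2484467	2486928	N15:deletion	2461	.	deletion	sequence	1
chr2	2490078	2490221	N15:deletion	143	.	deletion	sequence	1
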