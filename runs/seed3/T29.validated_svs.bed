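chr1	169978	169978	T29:insertion	3436	.	insertion	sequence	1
chr1	278016	278016	T29:insertion	5158	.	insertion	sequence	1
chr1	292872	292872	T29:insertion	2779	.	insertion	sequence	1
chr1	357954	357954	T29:insertion	1419	.	insertion	sequence	1
chr1	371377	380554	T29:deletion	9177	.	deletion	sequence	1
chr1	422496	423612	T29:deletion	1116	.	deletion	sequence	1
chr1	619725	621400	T29:deletion	1675	.	deletion	sequence	1
chr1	643664	650361	T29:deletion	6697	.	deletion	sequence	1
chr1	671328	671328	T29:insertion	1613	.	insertion	sequence	1
chr1	856299	856299	T29:insertion	2798	.	insertion	sequence	1
chr1	870440	870440	T29:insertion	726	.	insertion	sequence	1
chr1	879845	879845	T29:insertion	588	.	insertion	sequence	1
chr1	1192622	1192695	T29:repeat_contraction	216	.	repeat_contraction	sequence	1
chr1	1382187	1385981	T29:deletion	3794	.	deletion	sequence	1
chr1	1425070	1425070	T29:insertion	5415	.	insertion	sequence	1
chr1	1442641	1446566	T29:deletion	3925	.	deletion	sequence	1
chr1	1549589	1550165	T29:tandem_expansion	1088	.	tandem_expansion	sequence	1
chr1	1633663	1639193	T29:deletion	5530	.	deletion	sequence	1
chr1	1914026	1914026	T29:insertion	1786	.	insertion	sequence	1
chr1	1999220	1999850	T29:tandem_expansion	1170	.	tandem_expansion	sequence	1
chr1	2010179	2010729	T29:tandem_expansion	1100	.	tandem_expansion	sequence	1
chr1	2520886	2521328	T29:tandem_expansion	567	.	tandem_expansion	sequence	1
chr1	2524653	2524653	T29:insertion	1028	.	insertion	sequence	1
chr1	2535195	2535195	T29:insertion	7412	.	insertion	sequence	1
chr1	2539761	2540433	T29:repeat_expansion	308	.	repeat_expansion	sequence	1
chr2	21143	21143	T29:insertion	9435	.	insertion	sequence	1
chr2	80780	90012	T29:deletion	9232	.	deletion	sequence	1
chr2	225808	225808	T29:insertion	6116	.	insertion	sequence	1
chr2	730989	731675	T29:tandem_expansion	1216	.	tandem_expansion	sequence	1
chr2	829288	834629	T29:deletion	5341	.	deletion	sequence	1
chr2	850426	852761	T29:deletion	2335	.	deletion	sequence	1
chr2	940961	940961	T29:insertion	1376	.	insertion	sequence	1
chr2	1052240	1056623	T29:deletion	4383	.	deletion	sequence	1
chr2	1059657	1059745	T29:repeat_contraction	319	.	repeat_contraction	sequence	1
chr2	1387543	1390271	T29:deletion	2728	.	deletion	sequence	1
chr2	1644371	1647630	T29:deletion	3259	.	deletion	sequence	1
chr2	1859443	1861599	T29:deletion	2156	.	deletion	sequence	1
chr2	1868891	1873908	T29:deletion	5017	.	deletion	sequence	1
chr2	2015695	2015695	T29:insertion	5116	.	insertion	sequence	1
chr2	2145906	2146390	T29:tandem_expansion	990	.	tandem_expansion	sequence	1
chr2	2148504	2148504	T29:insertion	397	.	insertion	sequence	1
chr2	2247034	2247034	T29:insertion	5858	.	insertion	sequence	1
chr2	2263276	2265220	T29:deletion	1944	.	deletion	sequence	1
chr2	2306217	2306217	T29:insertion	2063	.	insertion	sequence	1
chr2	2312946	2312946	T29:insertion	73	.	insertion	sequence	1
chr2	2333943	2333943	T29:insertion	9756	.	insertion	sequence	1
chr2	2458013	2458013	T29:insertion	4014	.	insertion	sequence	1
chr2	2484467	2486928	T29:deletion	2461	.	deletion	sequence	1
chr2	2490078	2490221	T29:deletion	143	.	deletion	sequence	1
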