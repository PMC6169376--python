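chr1	92620	94421	I03:deletion	1801	.	deletion	sequence	1
chr1	213482	213482	I03:insertion	5634	.	insertion	sequence	1
chr1	247012	247012	I03:insertion	1897	.	insertion	sequence	1
chr1	278016	278016	I03:insertion	5158	.	insertion	sequence	1
chr1	463710	463710	I03:insertion	9816	.	insertion	sequence	1
chr1	643664	650361	I03:deletion	6697	.	deletion	sequence	1
chr1	1943924	1943924	I03:insertion	3048	.	insertion	sequence	1
chr1	1952744	1953504	I03:repeat_expansion	680	.	repeat_expansion	sequence	1
chr1	2080043	2082356	I03:deletion	2313	.	deletion	sequence	1
chr1	2172888	2177801	I03:deletion	4913	.	deletion	sequence	1
chr1	2398475	2403763	I03:deletion	5288	.	deletion	sequence	1
chr1	2524653	2524653	I03:insertion	1028	.	insertion	sequence	1
chr2	506364	507384	I03:deletion	1020	.	deletion	sequence	1
chr2	829288	834629	I03:deletion	5341	.	deletion	sequence	1
chr2	1089660	1090320	I03:tandem_expansion	1155	.	tandem_expansion	sequence	1
chr2	1093071	1095024	I03:deletion	1953	.	deletion	sequence	1
chr2	1108751	1110571	I03:deletion	1820	.	deletion	sequence	1
chr2	1193929	1193929	I03:insertion	1116	.	insertion	sequence	1
chr2	1364868	1367488	I03:deletion	2620	.	deletion	sequence	1
chr2	1387543	1390271	I03:deletion	2728	.	deletion	sequence	1
chr2	1644371	1647630	I03:deletion	3259	.	deletion	sequence	1
chr2	1859443	1861599	I03:deletion	2156	.	deletion	sequence	1
chr2	2184129	2184129	I03:insertion	1134	.	insertion	sequence	1
chr2	2309256	2309256	I03:insertion	4045	.	insertion	sequence	1
chr2	2529018	2531845	I03:deletion	2827	.	deletion	sequence	1
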