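chr1	250196	251804	B10:deletion	1608	.	deletion	sequence	1
chr1	255393	256179	B10:deletion	786	.	deletion	sequence	1
chr1	278016	278016	B10:insertion	5158	.	insertion	sequence	1
chr1	463710	463710	B10:insertion	9816	.	insertion	sequence	1
chr1	580903	589555	B10:deletion	8652	.	deletion	sequence	1
chr1	643664	650361	B10:deletion	6697	.	deletion	sequence	1
chr1	812420	812420	B10:insertion	1475	.	insertion	sequence	1
chr1	1513201	1513201	B10:insertion	2802	.	insertion	sequence	1
chr1	1943924	1943924	B10:insertion	3048	.	insertion	sequence	1
chr1	1952744	1953504	B10:repeat_expansion	680	.	repeat_expansion	sequence	1
chr1	2286509	2288642	B10:deletion	2133	.	deletion	sequence	1
chr1	2349856	2355122	B10:deletion	5266	.	deletion	sequence	1
chr1	2398475	2403763	B10:deletion	5288	.	deletion	sequence	1
chr1	2524653	2524653	B10:insertion	1028	.	insertion	sequence	1
chr2	43159	43835	B10:tandem_expansion	1377	.	tandem_expansion	sequence	1
chr2	185615	190757	B10:deletion	5142	.	deletion	sequence	1
chr2	829288	834629	B10:deletion	5341	.	deletion	sequence	1
chr2	1015652	1016426	B10:deletion	774	.	deletion	sequence	1
chr2	1022325	1025011	B10:deletion	2686	.	deletion	sequence	1
chr2	1093071	1095024	B10:deletion	1953	.	deletion	sequence	1
chr2	1108751	1110571	B10:deletion	1820	.	deletion	sequence	1
chr2	1138587	1146174	B10:deletion	7587	.	deletion	sequence	1
chr2	1364868	1367488	B10:deletion	2620	.	deletion	sequence	1
chr2	1387543	1390271	B10:deletion	2728	.	deletion	sequence	1
chr2	1406154	1406154	B10:insertion	4619	.	insertion	sequence	1
chr2	1644371	1647630	B10:deletion	3259	.	deletion	sequence	1
chr2	1859443	1861599	B10:deletion	2156	.	deletion	sequence	1
chr2	2184129	2184129	B10:insertion	1134	.	insertion	sequence	1
chr2	2309256	2309256	B10:insertion	4045	.	insertion	sequence	1
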