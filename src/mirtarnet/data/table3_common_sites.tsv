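gene_id	mirna_id	miranda_start	miranda_end	targetscan_start	targetscan_end
BAD	hsa-miR-744	211	236	228	234
BCL2	hsa-miR-195	2520	2537	2521	2527
BCL2	hsa-miR-139-5p	1211	1234	1218	1224
BCL2	hsa-miR-25	4228	4253	4237	4243
BCL2	hsa-miR-24	1007	1027	1011	1017
BCL2L1	hsa-miR-486-5p	657	678	670	676
CASP3	hsa-miR-370	1311	1333	1324	1330
CCS	hsa-miR-486-5p	89	111	103	109
CYCS	hsa-miR-93	3333	3357	3348	3354
CYCS	hsa-miR-93	4143	4167	4158	4164
CYCS	hsa-miR-125b	1564	1590	1582	1588
CYCS	hsa-miR-17	3333	3357	3348	3354
CYCS	hsa-miR-17	4143	4167	4158	4164
CYCS	hsa-miR-25	2189	2212	2204	2210
CYCS	hsa-miR-25	2597	2619	2610	2616
CYCS	hsa-miR-92a	2596	2619	2610	2616
CYCS	hsa-miR-93	4143	4167	4158	4164
CYCS	hsa-miR-20a	4143	4167	4158	4164
CYCS	hsa-miR-221	1576	1599	1592	1598
CYCS	hsa-miR-93	3333	3357	3348	3354
MAP2K3	hsa-miR-103	286	307	299	305
MAP2K3	hsa-miR-107	283	307	299	305
MAP2K3	hsa-miR-760	16	39	32	38
MAP2K3	hsa-miR-874	83	106	99	105
MAP2K3	hsa-miR-324-3p	40	64	56	62
p53	hsa-miR-30e	270	294	286	292
SLC1A2	hsa-miR-628-5p	2533	2551	2541	2547
TNF	hsa-miR-185	353	382	375	381
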