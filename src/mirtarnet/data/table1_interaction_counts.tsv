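gene_id	hsa-miR-370	hsa-miR-874	hsa-miR-423-3p	hsa-miR-323-5p	hsa-miR-760	hsa-miR-149	hsa-miR-139-3p	hsa-miR-744	hsa-miR-324-3p	hsa-miR-339-3p	hsa-miR-654-5p	printed_total
ALS2	1	1	1	1	1	2	0	1	1	0	0	9
APAF1	1	1	1	0	3	1	2	0	0	0	1	10
BAD	4	1	2	0	2	3	3	3	1	0	0	19
BAX	1	1	3	1	3	1	1	0	0	1	1	13
BCL2	1	1	0	1	1	1	2	1	0	1	2	11
BCL2L1	1	3	0	0	0	0	1	1	0	0	1	7
BID	2	1	1	2	0	1	0	3	1	0	0	11
CASP1	0	0	0	0	1	0	0	0	1	0	0	2
GRIA1	1	1	1	0	1	2	0	0	1	0	1	8
GPX1	0	3	2	2	1	0	0	1	0	2	0	11
DERL1	0	1	1	0	0	1	0	0	1	0	1	4
DAXX	1	2	0	0	2	0	0	0	1	0	3	9
CYCS	3	2	2	1	0	2	0	0	1	1	0	12
CHP	3	0	0	1	0	1	1	0	0	0	0	6
CCS	0	3	0	0	0	4	1	0	1	0	1	10
CAT	1	1	1	1	1	1	0	0	0	0	0	6
CASP9	1	3	2	2	1	0	0	0	1	1	0	11
CASP3	1	1	0	1	1	1	0	0	0	0	0	5
TOMM40	4	3	2	2	3	1	2	1	1	0	1	20
TNFRSF1A	5	2	4	4	1	1	1	0	2	1	1	22
TNF	1	2	0	0	2	0	1	0	0	1	0	7
SOD2	0	0	0	0	0	0	0	0	0	0	0	0
SLC1A2	3	1	3	1	1	1	0	2	1	2	1	16
RAC1	4	0	0	0	1	0	0	1	0	1	0	7
RAB5A	1	0	2	1	0	1	0	2	0	1	1	9
p53	1	1	1	1	1	0	2	2	0	1	1	11
NOS1	2	1	3	3	2	2	2	1	0	0	1	17
NEFM	3	2	1	2	2	1	2	1	1	0	1	16
NEFL	3	1	4	1	1	0	1	0	1	1	0	13
NEFH	3	1	2	2	2	0	0	0	1	2	1	14
MAPK14	4	3	3	4	1	1	0	0	0	0	0	16
MAP3K5	2	3	1	5	2	2	0	0	0	2	0	17
MAP2K6	2	0	0	0	1	0	0	1	0	0	0	4
MAP2K3	2	4	0	3	2	1	1	0	1	1	1	16
PRPH	3	2	2	2	1	4	2	1	3	2	1	23
Total	65	52	45	44	41	36	25	22	21	21	21	392
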