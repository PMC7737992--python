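# Published distribution of linked enhancers by number of target genes
# (full-scale build over all four assays, 78 tissue/cell types).
# linked_genes: 17643
n_target_genes	n_enhancers
1	249820
2	99919
3	46024
4	22620
5	12404
6	6851
7	4097
8	2610
9	1757
10	1179
11	800
12	490
13	289
14	183
15	154
16	104
17	59
18	30
19	55
20	17
21	35
22	16
23	31
24	22
25	15
26	11
27	13
28	5
29	6
30	3
31	2
32	2
33	3
34	1
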