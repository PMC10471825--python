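chrom	n_initial_qtls	n_mqtls
1	25	9
2	32	8
3	7	2
4	18	7
5	14	8
6	33	5
7	5	2
8	15	3
9	5	2
10	8	3
11	18	6
12	12	5
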