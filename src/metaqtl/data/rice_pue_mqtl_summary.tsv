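mqtl_id	chrom	n_qtls	avg_pve	position_cM	ci95_cM	start_cM	stop_cM	n_genes
MQTL1.1	1	11	12.3	19.51	3.10	17.96	21.06	85
MQTL1.2	1	7	13.0	26.14	3.39	24.45	27.84	104
MQTL1.3	1	7	12.5	30.25	4.55	27.98	32.53	127
MQTL1.4	1	7	12.3	36.07	5.79	33.18	38.97	217
MQTL1.5	1	6	8.9	46.33	3.29	44.69	47.98	82
MQTL1.6	1	7	8.3	63.29	2.12	62.23	64.35	32
MQTL1.7	1	5	9.3	75.62	1.20	75.02	76.22	22
MQTL2.1	2	3	9.5	44.31	1.09	43.77	44.86	24
MQTL2.7	2	7	11.7	105.31	4.57	103.03	107.60	159
MQTL3.1	3	2	9.3	0.88	1.77	0.02	1.79	8
MQTL4.1	4	2	9.1	31.98	6.60	28.68	35.28	118
MQTL4.3	4	3	8.5	73.19	2.47	71.96	74.43	272
MQTL4.4	4	3	10.0	99.15	5.63	96.34	101.97	246
MQTL4.5	4	3	8.0	127.50	0.20	127.40	127.60	46
MQTL5.1	5	3	7.0	1.33	1.92	0.37	2.29	96
MQTL6.1	6	7	10.7	5.63	0.50	5.38	5.88	9
MQTL6.2	6	9	6.5	9.62	1.71	8.77	10.48	108
MQTL6.3	6	8	8.9	10.98	0.82	10.57	11.39	47
MQTL6.4	6	6	20.4	26.18	8.12	22.12	30.24	278
MQTL6.5	6	5	13.0	37.87	4.42	35.66	40.08	138
MQTL6.6	6	5	13.5	57.20	4.68	54.86	59.54	62
MQTL6.7	6	5	13.3	86.61	6.91	83.16	90.07	179
MQTL6.8	6	7	14.2	116.04	2.61	114.74	117.35	95
MQTL7.2	7	3	9.3	58.54	3.31	56.89	60.20	57
MQTL8.1	8	11	8.5	1.87	2.80	0.47	3.27	126
MQTL8.2	8	11	15.1	10.43	0.68	10.09	10.77	7
MQTL8.3	8	4	9.0	56.46	0.70	56.11	56.81	10
MQTL9.2	9	4	13.0	54.08	2.55	52.81	55.36	53
MQTL10.1	10	2	9.4	2.45	4.90	0.00	4.90	70
MQTL10.2	10	3	11.5	13.07	0.78	12.68	13.46	21
MQTL10.3	10	7	9.2	34.54	2.05	33.51	35.56	19
MQTL11.1	11	5	6.3	4.52	2.48	3.28	5.76	94
MQTL11.3	11	4	14.0	27.36	9.00	22.86	31.86	239
MQTL11.4	11	6	14.0	36.00	0.33	35.84	36.17	355
MQTL11.5	11	4	9.8	84.47	6.17	81.39	87.56	202
MQTL11.6	11	6	14.4	92.03	3.90	90.08	93.98	77
MQTL12.1	12	4	6.0	2.33	8.45	0.00	6.56	303
MQTL12.2	12	6	11.0	16.99	6.90	13.54	20.44	250
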