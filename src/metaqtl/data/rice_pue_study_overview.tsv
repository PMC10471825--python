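study_id	population_type	population_size	n_qtls	year
S01	CSSL	75	7	2018
S02	DH	127	6	2000
S03	F2	262	21	2019
S04	RIL	284	6	2001
S05	RIL	330	15	2021
S06	F2_3	91	15	2013
S07	CSSL+F2	35+176	3	2022
S08	RIL	172	30	2017
S09	RIL	285	10	1998
S10	CSSL	48	3	2014
S11	DH	116	17	2008
S12	BIL	201	10	2022
S13	F2_3	82	11	2004
S14	RIL	113	36	2014
S15	BIL	98	13	1998
S16	BIL	60	20	2015
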