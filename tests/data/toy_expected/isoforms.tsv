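# apaswitch v0.1.0 | seed=0
transcript_id	gene_id	utr3_length	fpkm_CT	fpkm_IN	p_CT	p_IN
T1a	G1	100	10	0	1	0
T1b	G1	300	0	10	0	1
T2a	G2	100	5	2	0.5	0.2
T2b	G2	200	3	3	0.3	0.3
T2c	G2	400	2	5	0.2	0.5
T3a	G3	150	4	8	0.5	0.5
T3b	G3	250	4	8	0.5	0.5
T4a	G4	500	8	1	0.8	0.2
T4b	G4	100	2	4	0.2	0.8
T5a	G5	200	5	15	1	1
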