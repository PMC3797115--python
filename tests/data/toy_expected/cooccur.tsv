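# apaswitch v0.1.0 | seed=0
mirna_a	mirna_b	r_binary	p_binary	r_weighted	p_weighted	n_rows_used	computable	q_binary	q_weighted	significant
miR-A	miR-C	-1	0	-0.7137464271	0.2862535729	4	True	0	0.2862535729	True
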