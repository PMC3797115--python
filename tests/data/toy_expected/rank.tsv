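# apaswitch v0.1.0 | seed=0
gene_id	rank	rank_fraction	delta_len
G2	3	0.75	90
G1	4	1	200
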