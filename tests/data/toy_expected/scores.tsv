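# apaswitch v0.1.0 | seed=0
gene_id	mirna_id	score
G1	miR-A	1
G2	miR-A	0.3
G2	miR-B	0.3
G4	miR-C	-0.6
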