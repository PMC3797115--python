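# apaswitch v0.1.0 | seed=0 n_perm=100
mirna_id	true_r2	win_fraction	n_permutations
miR-A	0.9997767167	0.99	100
miR-B	0.2492107298	0	100
miR-C	0.7039904064	0.6	100
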