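# apaswitch v0.1.0 | seed=0
gene_id	n_transcripts	delta_len	trend_r	cmh_stat	p_value	q_value	trend_class
G1	2	200	1	19	1.307184537e-05	5.228738147e-05	positive
G2	3	90	0.3527378108	2.3640553	0.124159055	0.1655454067	positive
G3	2	0	0	0	1	1	none
G4	2	-240	-0.5773502692	4.666666667	0.03075356126	0.06150712252	negative
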