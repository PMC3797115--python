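# apaswitch v0.1.0 | seed=0 day=5
predictors	n_mirnas	r_squared	bic	min_coef_p
logfc_mrna+miR-A	1	0.9997767167	-25.7469178	0.0001486339106
logfc_mrna+miR-C	1	0.7039904064	10.20161101	0.2215801577
logfc_mrna	0	0.248825867	13.24840124	0.3922989169
logfc_mrna+miR-B	1	0.2492107298	14.85527676	0.977364888
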