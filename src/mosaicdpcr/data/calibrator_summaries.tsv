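assay_id	target_variant	rma_percent	mean_cpm	sd_cpm	n_reps
GNAS_27887_mu	c.604C>T	0	0.102	0.017	3
GNAS_27887_mu	c.604C>T	3	0.391	0.074	3
GNAS_27887_mu	c.604C>T	6	0.563	0.052	3
GNAS_27887_mu	c.604C>T	12.5	1.321	0.157	3
GNAS_27887_mu	c.604C>T	25	3.035	0.411	3
GNAS_27887_mu	c.604C>T	50	6.855	0.494	3
GNAS_27887_mu	c.604C>T	100	12.11	0.023	3
GNAS_27895_mu	c.605G>A	0	0.068	0.06	3
GNAS_27895_mu	c.605G>A	1.5	0.464	0.012	3
GNAS_27895_mu	c.605G>A	3	0.976	0.189	3
GNAS_27895_mu	c.605G>A	6	1.171	0.181	3
GNAS_27895_mu	c.605G>A	12.5	2.44	0.346	3
GNAS_27895_mu	c.605G>A	25	5.17	0.873	3
GNAS_27895_mu	c.605G>A	100	17.47	0.177	3
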