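response	date_label	link	alpha	beta_w	beta_p	beta_int	se_w	se_p	se_int	p_w	p_p	p_int	n_obs
barnacle_abundance	june	log	NaN	-0.693	2.087	0.414	0.149	0.120	0.182	0.0005	0.0005	0.023	24
barnacle_abundance	season	log	NaN	-0.887	2.087	0.507	0.214	0.210	0.299	0.0005	0.0005	0.090	168
grazer_occurrence	season	logit	NaN	-1.640	2.865	3.737	1.225	0.768	2.597	0.181	0.0005	0.150	168
macroalgae_cover	season	logit	NaN	-0.608	0.632	0.317	0.297	0.285	0.410	0.041	0.027	0.439	168
cyanobacteria_concentration	season	identity	NaN	-0.011	0.268	0.086	0.009	0.026	0.039	0.188	0.0005	0.030	168
diatom_concentration	season	identity	NaN	-0.004	0.230	-0.003	0.047	0.047	0.066	0.927	0.0005	0.963	168
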