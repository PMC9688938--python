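dataset_id	metric_x	metric_y	rho	p_value	n_samples	significant	direction	q_value
D0	NES:PDL1	Mes	0.3681022506	0.003807569866	60	True	positive	0.01227649195
D1	NES:PDL1	Mes	0.3498749653	0.006138245973	60	True	positive	0.01227649195
D2	NES:PDL1	Mes	0.310252848	0.01584291584	60	True	positive	0.02112388779
D3	NES:PDL1	Mes	0.1397054737	0.2870472933	60	False	positive	0.2870472933
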