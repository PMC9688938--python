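dataset_id	metric_x	metric_y	rho	p_value	n_samples	significant	direction	q_value
D0	NES:PDL1	NES:OXPHOS	-0.4944151153	5.940942076e-05	60	True	negative	7.921256102e-05
D1	NES:PDL1	NES:OXPHOS	-0.5903862184	6.870983302e-07	60	True	negative	2.748393321e-06
D2	NES:PDL1	NES:OXPHOS	-0.3374270631	0.008375848893	60	True	negative	0.008375848893
D3	NES:PDL1	NES:OXPHOS	-0.544929147	6.743806052e-06	60	True	negative	1.34876121e-05
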