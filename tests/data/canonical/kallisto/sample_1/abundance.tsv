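target_id	length	eff_length	est_counts	tpm
G1T1	541	343.69209991637	23.1202194864288	378739.506619578
G1T2	2390	2231.66451800338	20.9286157923594	52799.4991428232
G2T1	2067	1888.36328231808	51.9392148174837	154856.000574158
G2T2	1485	1282.44983720783	27.6346509807439	121319.832821026
G3T1	1469	1290.66259083396	46.7806903270357	204066.685136304
G3T2	2619	2450.23041370009	38.3926659133192	88218.4757061118
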