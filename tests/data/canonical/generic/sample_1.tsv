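tx	n_reads	eff_len
G1T1	23.1202194864288	343.69209991637
G1T2	20.9286157923594	2231.66451800338
G2T1	51.9392148174837	1888.36328231808
G2T2	27.6346509807439	1282.44983720783
G3T1	46.7806903270357	1290.66259083396
G3T2	38.3926659133192	2450.23041370009
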