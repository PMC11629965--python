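target_id	length	eff_length	est_counts	tpm
G1T1	541	335.464579025188	78.944950786385	443327.940085511
G1T2	2390	2212.87583789435	131.426833996333	111885.656529026
G2T1	2067	1839.22752608821	45.3830023086471	46484.1806721362
G2T2	1485	1278.35901844555	185.404762160697	273221.870732731
G3T1	1469	1276.30259349529	35.5760328945986	52511.1200235224
G3T2	2619	2413.52475787853	92.9730053117798	72569.231957073
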