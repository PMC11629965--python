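transcript_id	gene_id	length	effective_length	expected_count	TPM	FPKM	IsoPct
G1T1	G1	541	335.464579025188	78.944950786385	443327.940085511	413071.205231584	79.8481778524052
G1T2	G1	2390	2212.87583789435	131.426833996333	111885.656529026	104249.560678845	20.1518221475948
G2T1	G2	2067	1839.22752608821	45.3830023086471	46484.1806721362	43311.6769737959	14.5396624392542
G2T2	G2	1485	1278.35901844555	185.404762160697	273221.870732731	254574.722760375	85.4603375607458
G3T1	G3	1469	1276.30259349529	35.5760328945986	52511.1200235224	48927.2831123456	41.9819093822736
G3T2	G3	2619	2413.52475787853	92.9730053117798	72569.231957073	67616.4468710377	58.0180906177264
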