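Name	Length	EffectiveLength	TPM	NumReads
G1T1	541	335.464579025188	443327.940085511	78.944950786385
G1T2	2390	2212.87583789435	111885.656529026	131.426833996333
G2T1	2067	1839.22752608821	46484.1806721362	45.3830023086471
G2T2	1485	1278.35901844555	273221.870732731	185.404762160697
G3T1	1469	1276.30259349529	52511.1200235224	35.5760328945986
G3T2	2619	2413.52475787853	72569.231957073	92.9730053117798
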