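tx	n_reads	eff_len
G1T1	78.944950786385	335.464579025188
G1T2	131.426833996333	2212.87583789435
G2T1	45.3830023086471	1839.22752608821
G2T2	185.404762160697	1278.35901844555
G3T1	35.5760328945986	1276.30259349529
G3T2	92.9730053117798	2413.52475787853
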