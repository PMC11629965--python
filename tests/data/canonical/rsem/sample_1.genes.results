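gene_id	transcript_id(s)	length	effective_length	expected_count	TPM	FPKM
G1	G1T1,G1T2	767.228156925475	574.688595573459	44.0488352787882	431539.005762401	367095.919403445
G2	G2T1,G2T2	1811.33627362028	1622.19474410424	79.5738657982275	276175.833395184	234933.621580983
G3	G3T1,G3T2	1816.09681042181	1640.64719325534	85.1733562403549	292285.160842415	248637.292144354
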