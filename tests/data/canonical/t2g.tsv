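transcript_id	gene_id	gene_name	biotype
G1T1	G1	G1-name	protein_coding
G1T2	G1	G1-name	protein_coding
G2T1	G2	G2-name	lincRNA
G2T2	G2	G2-name	lincRNA
G3T1	G3	G3-name	snoRNA
G3T2	G3	G3-name	snoRNA
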