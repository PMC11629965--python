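feature_id	sample_1	sample_2
G1T1	66.2092170081	223.710446933
G1T2	9.23012634163	56.4593114134
G2T1	33.2248153062	28.7887651543
G2T2	26.0295308126	169.212840967
G3T1	51.7365456531	38.4290740071
G3T2	22.3658221957	53.1081489838
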