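feature_id	sample_1	sample_2
G1	44.0488352788	210.371784783
G2	79.5738657982	230.787764469
G3	85.1733562404	128.549038206
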