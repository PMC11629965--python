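feature_id	sample_1	sample_2
G1	574.688595573	713.797156891
G2	1622.1947441	1359.90740618
G3	1640.64719326	1936.09717935
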