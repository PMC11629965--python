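feature_id	sample_1	sample_2
G1	47.8742564235	192.594419856
G2	70.9105009415	256.671328712
G3	90.0112999524	120.442838891
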