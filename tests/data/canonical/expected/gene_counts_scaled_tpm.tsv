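feature_id	sample_1	sample_2
G1	90.1036429818	316.309953865
G2	57.6644251393	182.139282948
G3	61.0279891963	71.2593506457
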