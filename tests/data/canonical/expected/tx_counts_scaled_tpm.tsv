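feature_id	sample_1	sample_2
G1T1	79.0793157325	252.567734527
G1T2	11.0243272494	63.742219338
G2T1	32.3333223718	26.4824369099
G2T2	25.3311027674	155.656846038
G3T1	42.6083192863	29.9160360145
G3T2	18.41966991	41.3433146312
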