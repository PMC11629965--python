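feature_id	sample_1	sample_2
G1	431539.005762	555213.596615
G2	276175.833395	319706.051405
G3	292285.160842	125080.351981
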