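gene_id	transcript_id(s)	length	effective_length	expected_count	TPM	FPKM
G1	G1T1,G1T2	913.607191509028	713.797156891423	210.371784782718	555213.596614538	517320.76591043
G2	G2T1,G2T2	1569.62083539646	1359.90740618488	230.787764469344	319706.051404867	297886.399734171
G3	G3T1,G3T2	2136.20804210385	1936.09717935203	128.549038206378	125080.351980595	116543.729983383
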