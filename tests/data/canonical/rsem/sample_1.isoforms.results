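transcript_id	gene_id	length	effective_length	expected_count	TPM	FPKM	IsoPct
G1T1	G1	541	343.69209991637	23.1202194864288	378739.506619578	322181.136676833	87.7648373755827
G1T2	G1	2390	2231.66451800338	20.9286157923594	52799.4991428232	44914.7827266112	12.2351626244173
G2T1	G2	2067	1888.36328231808	51.9392148174837	154856.000574158	131730.863599408	56.0715246770244
G2T2	G2	1485	1282.44983720783	27.6346509807439	121319.832821026	103202.757981575	43.9284753229756
G3T1	G3	1469	1290.66259083396	46.7806903270357	204066.685136304	173592.760791987	69.8176686589729
G3T2	G3	2619	2450.23041370009	38.3926659133192	88218.4757061118	75044.5313523664	30.1823313410271
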