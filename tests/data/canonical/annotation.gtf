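#!genome synthetic toy annotation
chr1	synthetic	gene	1000	3890	.	+	.	gene_id "G1"; gene_name "G1-name"; gene_biotype "protein_coding";
chr1	synthetic	transcript	1000	1541	.	+	.	gene_id "G1"; transcript_id "G1T1"; gene_name "G1-name"; gene_biotype "protein_coding";
chr1	synthetic	exon	1000	1541	.	+	.	gene_id "G1"; transcript_id "G1T1"; gene_name "G1-name"; gene_biotype "protein_coding";
chr1	synthetic	transcript	1000	3390	.	+	.	gene_id "G1"; transcript_id "G1T2"; gene_name "G1-name"; gene_biotype "protein_coding";
chr1	synthetic	exon	1000	3390	.	+	.	gene_id "G1"; transcript_id "G1T2"; gene_name "G1-name"; gene_biotype "protein_coding";
chr1	synthetic	gene	4890	7457	.	+	.	gene_id "G2"; gene_name "G2-name"; gene_biotype "lincRNA";
chr1	synthetic	transcript	4890	6957	.	+	.	gene_id "G2"; transcript_id "G2T1"; gene_name "G2-name"; gene_biotype "lincRNA";
chr1	synthetic	exon	4890	6957	.	+	.	gene_id "G2"; transcript_id "G2T1"; gene_name "G2-name"; gene_biotype "lincRNA";
chr1	synthetic	transcript	4890	6375	.	+	.	gene_id "G2"; transcript_id "G2T2"; gene_name "G2-name"; gene_biotype "lincRNA";
chr1	synthetic	exon	4890	6375	.	+	.	gene_id "G2"; transcript_id "G2T2"; gene_name "G2-name"; gene_biotype "lincRNA";
chr1	synthetic	gene	8457	11576	.	+	.	gene_id "G3"; gene_name "G3-name"; gene_biotype "snoRNA";
chr1	synthetic	transcript	8457	9926	.	+	.	gene_id "G3"; transcript_id "G3T1"; gene_name "G3-name"; gene_biotype "snoRNA";
chr1	synthetic	exon	8457	9926	.	+	.	gene_id "G3"; transcript_id "G3T1"; gene_name "G3-name"; gene_biotype "snoRNA";
chr1	synthetic	transcript	8457	11076	.	+	.	gene_id "G3"; transcript_id "G3T2"; gene_name "G3-name"; gene_biotype "snoRNA";
chr1	synthetic	exon	8457	11076	.	+	.	gene_id "G3"; transcript_id "G3T2"; gene_name "G3-name"; gene_biotype "snoRNA";
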