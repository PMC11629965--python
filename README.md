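# txsum

Bias-corrected gene-level count estimation from transcript-level RNA-seq
quantifications, for Python-centric bulk RNA-seq analysis.

Transcript quantifiers — Salmon/Sailfish, kallisto, RSEM, piscem-infer,
oarfish — produce per-transcript estimates of read counts `c[t,s]`, TPM
abundances `a[t,s]` and effective lengths `l[t,s]`. Differential gene
expression tools (PyDESeq2, DESeq2, edgeR, limma) want gene-level counts,
and summing transcript counts naively leaves two biases in place: longer
transcripts accrue more reads at equal molar expression, and shifts in
isoform usage between conditions change a gene's apparent expression.
txsum reads the quantifier output, joins it to a transcript-to-gene
mapping, and produces gene-level matrices

    C[g,s] = Σ_{t∈g} c[t,s]          (counts)
    A[g,s] = Σ_{t∈g} a[t,s]          (abundance, TPM)
    L[g,s] = Σ_{t∈g} a[t,s]·l[t,s] / Σ_{t∈g} a[t,s]   (effective length)

optionally replacing `C` with abundance-derived pseudo-counts —
`scaledTPM`, `lengthScaledTPM`, or (transcript-level, for differential
transcript usage) `dtuScaledTPM` — rescaled per sample so column sums
equal the original library sizes. Bootstrap/Gibbs inferential replicates
are carried through summarization with their per-entry variance.
Mappings can be built from a GTF or any delimited table; results can be
restricted to chosen gene biotypes; output is an AnnData-compatible
`.h5ad` container or plain TSV/CSV matrices. A command-line interface
mirrors the library exactly. See `docs/methods.md` for the full model
and the numerical choices.

## Worked example

The built-in generator writes internally consistent quantifier output in
every supported dialect (here: 3 genes × 2 isoforms, 2 samples, seed 42):

```python
from txsum import synthetic, read_salmon, build_dataset, summarize_to_gene
import numpy as np

gt = synthetic.generate(synthetic.SyntheticSpec(
    n_genes=3, isoforms_per_gene=2, n_samples=2, n_bootstrap=4, seed=42),
    "demo")
samples = [read_salmon(f"demo/salmon/sample_{i}") for i in (1, 2)]
ds = build_dataset(samples)
genes = summarize_to_gene(ds, gt.t2g, mode="length_scaled_tpm")
print(genes.feature_ids)
print(np.round(genes.counts, 2))
print("library sizes:", np.round(ds.counts.sum(axis=0), 2),
      "->", np.round(genes.counts.sum(axis=0), 2))
```

prints

```
['G1', 'G2', 'G3']
[[ 47.87 192.59]
 [ 70.91 256.67]
 [ 90.01 120.44]]
library sizes: [208.8  569.71] -> [208.8  569.71]
```

Each row is a gene, each column a sample. The counts are
`lengthScaledTPM` pseudo-counts: the TPM of each gene's isoforms times
the gene's cross-sample mean effective length, rescaled so every
sample's column sum still equals its original library size (208.8 and
569.71 estimated reads) — length and isoform-usage bias are corrected
while library sizes, the quantity downstream normalization relies on,
are conserved exactly.

The same run from the shell, with plain-text output:

```sh
txsum -i demo/salmon/sample_1 -i demo/salmon/sample_2 -t salmon \
      -m demo/t2g.tsv -c length_scaled_tpm \
      --output-format tsv -o demo/gene_counts
```

```
feature_id  sample_1       sample_2
G1          47.8742564235  192.594419856
G2          70.9105009415  256.671328712
G3          90.0112999524  120.442838891
```

(`demo/gene_counts/counts.tsv`; `abundance.tsv`, `length.tsv` and
`features.tsv` are written alongside.) The library call and the CLI
produce byte-identical files. Useful variants: `--tx-out` keeps
transcript-level output (`-c dtu_scaled_tpm` for differential transcript
usage), `--biotype protein_coding` restricts to a biotype, a GTF can be
passed to `-m` directly, and `--inferential-replicates` carries
bootstrap samples into the `.h5ad` output
(`--include-variance`/`--include-replicates`).

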