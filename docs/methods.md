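# Methods

## The problem

Transcript quantifiers (Salmon/Sailfish, kallisto, RSEM, piscem-infer,
oarfish) estimate per-transcript read counts, TPM abundances and
effective lengths from bulk RNA-seq reads. Differential *gene* expression
tools need gene-level counts, and a naive sum of transcript counts is
biased: a gene whose expressed isoform mix shifts toward longer
transcripts accrues more reads at constant molar expression. txsum joins
transcript estimates to a transcript-to-gene mapping, summarizes them to
gene level, and optionally replaces counts with abundance-derived
pseudo-counts that correct length and isoform-usage bias.

## Summarization model

Let `c[t,s]`, `a[t,s]`, `l[t,s]` be the estimated count, TPM and
effective length of transcript `t` in sample `s`, and `g(t)` the gene of
`t`. Gene-level quantities are

* counts: `C[g,s] = Σ_{t∈g} c[t,s]`
* abundance: `A[g,s] = Σ_{t∈g} a[t,s]`
* length: the abundance-weighted mean
  `L[g,s] = Σ_{t∈g} a[t,s]·l[t,s] / Σ_{t∈g} a[t,s]`.

The weighted mean makes the gene length the *expected effective length
of a sampled transcript of that gene*, which is the offset downstream
count models need. When `Σ_{t∈g} a[t,s] = 0` the mean is undefined; the
fallback is the mean over the gene's transcripts of each transcript's
cross-sample mean effective length, which stays inside the transcript
length range and never invents a value outside the data. Genes with a
single transcript reproduce that transcript's rows verbatim in all three
matrices (implemented as a direct copy, since a one-element weighted
mean `(a·l)/a` is not bit-exact in floating point).

Gene output order is the first-appearance order of genes along the
transcript axis — deterministic and stable under re-runs; downstream
sorts are the consumer's explicit choice. All accumulation is plain
double-precision summation; gene groups are small (tens of isoforms at
most), so compensated summation would buy nothing at the tolerances we
test (1e-10 relative against the oracle).

## Counts-from-abundance modes

`library_sizes` are the column sums of the *original* count matrix; they
are the conserved quantity under every transform. With TPM matrix `a`
and per-feature factor `f`:

| mode | factor `f_i` | level |
|---|---|---|
| `no` | — (counts unchanged) | both |
| `scaled_tpm` | 1 | both |
| `length_scaled_tpm` | cross-sample mean of feature `i`'s effective length | both |
| `dtu_scaled_tpm` | median over gene `g(i)`'s transcripts of their cross-sample mean lengths | transcript only |

The transformed matrix is `x[i,s] = a[i,s]·f_i` rescaled per column so
`Σ_i x[i,s]` equals the original library size of sample `s`. A sample
with zero total abundance yields a zero column with a logged warning
(possible after aggressive biotype filtering) rather than an error.
The median over an even number of isoforms is the midpoint of the two
central values. `dtu_scaled_tpm` keeps transcript-level output: isoforms
of one gene share a single length factor, so within-gene proportions —
the quantity of interest in differential transcript usage — are
preserved exactly. At gene level, transforms operate on the gene-level
matrices (the gene count column sum equals the transcript one by
conservation, so the library size is unambiguous).

The cross-sample mean length (rather than a per-sample length) is used
in `length_scaled_tpm` and `dtu_scaled_tpm` so that the length factor is
a feature constant and cannot re-introduce between-sample length
variation into the corrected counts; this choice is pinned by the
in-repo oracle.

## Inferential replicates

Salmon and kallisto can emit bootstrap or Gibbs resamples of their
posterior over transcript counts, quantifying read-assignment
uncertainty. txsum carries them as a feature × sample × replicate
tensor: each replicate slice is summed per gene exactly like the count
matrix, and the per-entry unbiased variance (divisor n−1) is exposed.
Counts-from-abundance transforms are *not* applied to replicate tensors
— replicates stay raw summed counts, since mode-transformed replicates
have no established downstream consumer and the raw sums are what
uncertainty-aware tests expect. Replicates are optional end to end;
every path works identically without them.

Salmon replicate payloads are decoded from
`aux_info/bootstrap/bootstraps.gz` as a flat little-endian float64 array
in replicate-major order, with the replicate count taken from
`meta_info.json` (`num_bootstraps`) and Gibbs samples distinguished by
`samp_type`. kallisto replicates come from the HDF5 `bootstrap/bs*`
datasets in index order.

## Identifier handling

Quantifier ids and mapping ids frequently disagree on version suffixes
(`ENST….10`) or carry pipe-delimited FASTA headers. `normalize_id`
truncates at the first `|` (first) and strips a trailing `.digits`
(second); the same flags are applied to both sides of the join.
Transcripts present in the quantification but absent from the mapping
are a hard error listing up to ten offenders — silent dropping corrupts
library sizes — with an explicit `drop_unmapped` override. GTF biotype
lookup searches `gene_biotype`, then `transcript_biotype`, then
`gene_type`, covering Ensembl and GENCODE attribute dialects. Biotype
filtering never rescales counts or lengths; rescaling the retained TPM
columns back to 1e6 is an explicit opt-in flag, because whether
"abundance" should mean the original or the restricted transcriptome is
an analysis decision, not a file-format one.

## Synthetic data generator

`txsum.synthetic` emulates a quantifier's output, not its inference:

* true transcript counts are log-normal (natural-log mean 4.0, sd 1.0 by
  default — fractional counts in the tens-to-hundreds, the typical scale
  of a moderately expressed transcript in a bulk library);
* transcript lengths are uniform on 300–3000 bases, effective lengths
  are `length − 200` (a nominal fragment-length correction) jittered
  ±2% per sample, so cross-sample mean lengths are exercised
  non-trivially;
* TPM is derived from the standard definition, so columns sum to 1e6 by
  construction;
* bootstrap replicates are multinomial resamples of each sample's read
  mass with probabilities proportional to true counts — the correct
  sampling model for read-level bootstrap *given* unambiguous
  assignment.

What it does not emulate: read-mapping ambiguity (replicate variance
here is pure multinomial noise, whereas real inferential variance is
inflated for transcripts with shared sequence), biological covariance
between samples, GC/positional bias, and multi-gene ambiguity. Passing
tests therefore demonstrate algorithmic correctness of summarization,
transforms and serialization — not robustness to quantifier estimation
error, which is the quantifier's problem, not the summarizer's.

Everything is deterministic per seed, byte-for-byte, including the HDF5
and gzip outputs (object timestamps pinned). Text files print 15
significant digits so parse round-trips land well inside the 1e-6
relative test tolerance. The canonical fixture (3 genes × 2 isoforms,
2 samples, 4 bootstraps, seed 42) ships in `tests/data/canonical/` as
text goldens plus oracle-produced expected outputs; the binary members
are regenerated from the same seed at test time and the text members are
asserted byte-identical to the committed copies.

## The oracle

`oracle_summarize` re-implements summarization and all four modes as
explicit per-gene Python loops, sharing no code with the main
implementation. The equivalence suite runs the canonical fixture plus
100 randomized instances (≤10 genes, ≤5 isoforms each, ≤6 samples)
through both paths and requires agreement to 1e-10 relative on counts,
abundance and length for every configuration. `scripts/acceptance.py`
re-measures this from scratch, along with library-size conservation,
format round-trip error, bootstrap recovery (fraction of gene×sample
entries whose 200-replicate mean falls within 3 standard errors of the
true gene count, on a 20-gene × 4-sample instance), and CLI/library
byte-identity. Problem sizes throughout (tens of genes, hundreds of
replicates) are chosen as the smallest instances that exercise every
code path non-degenerately; the algorithms are closed-form, so scale
adds no information.

## Degenerate inputs and tie-breaks

* Zero effective length with zero count: tolerated, coerced to 1 for
  safe division, logged. Zero length with positive count: error.
* All-zero count vector: TPM derivation returns all zeros rather than
  dividing by zero.
* Duplicate transcript ids in one file: error. Duplicate
  transcript-to-gene rows: deduplicated with a warning when consistent,
  error when conflicting.
* Samples disagreeing on the transcript id set: error naming the first
  divergent sample and up to ten differing ids. Row *order* may differ;
  later samples are realigned to the first sample's order.
* Exported counts are kept fractional; `--round-counts` rounds
  half-to-even at export only.

## Known limitations

* No alevin-style single-cell matrix input; no GFF3 attribute dialect;
  no streaming parse of files larger than memory.
* No network annotation retrieval — BioMart-style mappings are ingested
  from locally saved tables.
* The Salmon bootstrap byte layout above is the writer/reader contract
  of this package's own fixtures; other producers' compressed layouts
  may differ.
* h5ad export stores matrices dense; bulk gene×sample scales make
  sparsity pointless and dense storage keeps round-trips exact.
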