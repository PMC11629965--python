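"""Synthetic quantification fixtures and an independent summarization oracle.

The generator emits an internally consistent multi-sample transcriptome
quantification — true transcript counts drawn log-normally, effective
lengths drawn per transcript and jittered per sample, TPM derived from
the standard definition, and optional bootstrap replicates drawn by
multinomial resampling of each sample's read mass — and serializes it in
every on-disk dialect the readers understand (Salmon directory with
bootstrap payload, kallisto TSV and HDF5, RSEM isoform/gene tables, a
generic three-column TSV, a toy GTF, and a transcript-to-gene TSV).
Everything is deterministic for a fixed seed, byte-for-byte.

:func:`oracle_summarize` is a deliberately naive reference implementation
of gene-level summarization and the counts-from-abundance modes, written
with explicit per-gene loops and sharing no code with the main
implementation; it exists purely as an independent check.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import UsageError
from .quant_io import derive_tpm
from .txgene_map import TranscriptGeneMap

BIOTYPE_CYCLE = ("protein_coding", "lincRNA", "snoRNA")

#: numeric formatting for all generated text files (>= 12 significant
#: digits so text round-trips are exact at test tolerance)
_FMT = "%.15g"


def _f(x: float) -> str:
    return _FMT % x


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic quantification experiment.

    ``isoforms_per_gene`` is either a fixed integer or an inclusive
    ``(low, high)`` range sampled per gene.  ``expression_log_mean`` /
    ``expression_log_sd`` parameterize the log-normal draw of true
    transcript counts (natural-log scale).  Effective lengths are drawn
    per transcript from ``length_range`` and jittered +/-2% per sample so
    cross-sample mean lengths are non-degenerate.
    """

    n_genes: int = 3
    isoforms_per_gene: int | tuple[int, int] = 2
    n_samples: int = 2
    n_bootstrap: int = 4
    length_range: tuple[float, float] = (300.0, 3000.0)
    expression_log_mean: float = 4.0
    expression_log_sd: float = 1.0
    seed: int = 42


#: the canonical small fixture used as the regression surface
CANONICAL_SPEC = SyntheticSpec(
    n_genes=3, isoforms_per_gene=2, n_samples=2, n_bootstrap=4, seed=42
)


@dataclass
class GroundTruth:
    """The generating tensors behind a synthetic fixture."""

    transcript_ids: list[str]
    gene_ids: list[str]  # per transcript, aligned
    sample_ids: list[str]
    lengths: np.ndarray  # per transcript, integer bases
    true_counts: np.ndarray  # transcript x sample
    effective_lengths: np.ndarray  # transcript x sample
    tpm: np.ndarray  # transcript x sample
    t2g: TranscriptGeneMap
    biotypes: list[str] = field(default_factory=list)  # per transcript
    replicate_tensor: np.ndarray | None = None  # transcript x sample x replicate

    @property
    def genes(self) -> list[str]:
        seen: list[str] = []
        for g in self.gene_ids:
            if g not in seen:
                seen.append(g)
        return seen


def generate(spec: SyntheticSpec, out_dir: str | Path | None = None) -> GroundTruth:
    """Draw a ground truth and (optionally) write every fixture dialect.

    With ``out_dir`` set, writes::

        out_dir/salmon/<sample>/quant.sf (+ aux_info/ when n_bootstrap > 0)
        out_dir/kallisto/<sample>/abundance.tsv + abundance.h5
        out_dir/rsem/<sample>.isoforms.results + <sample>.genes.results
        out_dir/generic/<sample>.tsv          (tx / n_reads / eff_len)
        out_dir/annotation.gtf
        out_dir/t2g.tsv
    """
    if spec.n_genes < 1:
        raise UsageError("synthetic spec needs at least one gene")
    if spec.n_samples < 1:
        raise UsageError("synthetic spec needs at least one sample")
    rng = np.random.default_rng(spec.seed)

    if isinstance(spec.isoforms_per_gene, int):
        n_iso = np.full(spec.n_genes, spec.isoforms_per_gene, dtype=int)
    else:
        lo, hi = spec.isoforms_per_gene
        n_iso = rng.integers(lo, hi + 1, size=spec.n_genes)
    if np.any(n_iso < 1):
        raise UsageError("every gene needs at least one isoform")

    gene_names = [f"G{g + 1}" for g in range(spec.n_genes)]
    transcript_ids: list[str] = []
    gene_ids: list[str] = []
    biotypes: list[str] = []
    for g, gene in enumerate(gene_names):
        biotype = BIOTYPE_CYCLE[g % len(BIOTYPE_CYCLE)]
        for k in range(n_iso[g]):
            transcript_ids.append(f"{gene}T{k + 1}")
            gene_ids.append(gene)
            biotypes.append(biotype)
    n_tx = len(transcript_ids)

    lengths = rng.integers(
        int(spec.length_range[0]), int(spec.length_range[1]) + 1, size=n_tx
    ).astype(float)
    eff_base = np.maximum(lengths - 200.0, 25.0)
    jitter = rng.uniform(0.98, 1.02, size=(n_tx, spec.n_samples))
    effective_lengths = eff_base[:, None] * jitter
    true_counts = rng.lognormal(
        mean=spec.expression_log_mean, sigma=spec.expression_log_sd,
        size=(n_tx, spec.n_samples),
    )
    tpm = np.column_stack(
        [derive_tpm(true_counts[:, s], effective_lengths[:, s]) for s in range(spec.n_samples)]
    )

    replicate_tensor = None
    if spec.n_bootstrap > 0:
        replicate_tensor = np.empty((n_tx, spec.n_samples, spec.n_bootstrap))
        for s in range(spec.n_samples):
            total = true_counts[:, s].sum()
            n_reads = int(round(total))
            probs = true_counts[:, s] / total
            draws = rng.multinomial(n_reads, probs, size=spec.n_bootstrap)
            replicate_tensor[:, s, :] = draws.T.astype(float)

    import pandas as pd

    t2g = TranscriptGeneMap(
        pd.DataFrame(
            {
                "transcript_id": transcript_ids,
                "gene_id": gene_ids,
                "gene_name": [f"{g}-name" for g in gene_ids],
                "biotype": biotypes,
            }
        )
    )
    gt = GroundTruth(
        transcript_ids=transcript_ids,
        gene_ids=gene_ids,
        sample_ids=[f"sample_{s + 1}" for s in range(spec.n_samples)],
        lengths=lengths,
        true_counts=true_counts,
        effective_lengths=effective_lengths,
        tpm=tpm,
        t2g=t2g,
        biotypes=biotypes,
        replicate_tensor=replicate_tensor,
    )
    if out_dir is not None:
        _write_fixtures(gt, Path(out_dir))
    return gt


# ---------------------------------------------------------------------------
# fixture writers (the writer/reader contract half owned by this module)


def _write_tsv(path: Path, header: list[str], rows) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def _write_fixtures(gt: GroundTruth, out: Path) -> None:
    for s, sample in enumerate(gt.sample_ids):
        _write_salmon_sample(gt, s, out / "salmon" / sample)
        _write_kallisto_sample(gt, s, out / "kallisto" / sample)
        _write_rsem_sample(gt, s, out / "rsem", sample)
        _write_tsv(
            out / "generic" / f"{sample}.tsv",
            ["tx", "n_reads", "eff_len"],
            (
                [gt.transcript_ids[t], _f(gt.true_counts[t, s]), _f(gt.effective_lengths[t, s])]
                for t in range(len(gt.transcript_ids))
            ),
        )
    _write_gtf(gt, out / "annotation.gtf")
    _write_tsv(
        out / "t2g.tsv",
        ["transcript_id", "gene_id", "gene_name", "biotype"],
        (
            [tx, g, f"{g}-name", b]
            for tx, g, b in zip(gt.transcript_ids, gt.gene_ids, gt.biotypes)
        ),
    )


def _write_salmon_sample(gt: GroundTruth, s: int, sample_dir: Path) -> None:
    _write_tsv(
        sample_dir / "quant.sf",
        ["Name", "Length", "EffectiveLength", "TPM", "NumReads"],
        (
            [
                gt.transcript_ids[t],
                "%d" % gt.lengths[t],
                _f(gt.effective_lengths[t, s]),
                _f(gt.tpm[t, s]),
                _f(gt.true_counts[t, s]),
            ]
            for t in range(len(gt.transcript_ids))
        ),
    )
    if gt.replicate_tensor is None:
        return
    aux = sample_dir / "aux_info"
    (aux / "bootstrap").mkdir(parents=True, exist_ok=True)
    n_boot = gt.replicate_tensor.shape[2]
    with open(aux / "meta_info.json", "w") as fh:
        json.dump({"num_bootstraps": n_boot, "samp_type": "bootstrap"}, fh, indent=1)
        fh.write("\n")
    # flat little-endian float64, replicate-major; mtime pinned so the
    # gzip stream is byte-reproducible
    payload = gt.replicate_tensor[:, s, :].T.astype("<f8").tobytes()
    with open(aux / "bootstrap" / "bootstraps.gz", "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
            gz.write(payload)


def _write_kallisto_sample(gt: GroundTruth, s: int, sample_dir: Path) -> None:
    import h5py

    _write_tsv(
        sample_dir / "abundance.tsv",
        ["target_id", "length", "eff_length", "est_counts", "tpm"],
        (
            [
                gt.transcript_ids[t],
                "%d" % gt.lengths[t],
                _f(gt.effective_lengths[t, s]),
                _f(gt.true_counts[t, s]),
                _f(gt.tpm[t, s]),
            ]
            for t in range(len(gt.transcript_ids))
        ),
    )
    n_boot = 0 if gt.replicate_tensor is None else gt.replicate_tensor.shape[2]
    with h5py.File(sample_dir / "abundance.h5", "w", track_order=False) as h5:
        def dset(name, data):
            h5.create_dataset(name, data=data, track_times=False)

        dset("aux/ids", np.array([t.encode() for t in gt.transcript_ids]))
        dset("aux/lengths", gt.lengths.astype("int64"))
        dset("aux/eff_lengths", gt.effective_lengths[:, s].astype("<f8"))
        dset("aux/num_bootstrap", np.array([n_boot], dtype="int64"))
        dset("est_counts", gt.true_counts[:, s].astype("<f8"))
        for b in range(n_boot):
            dset(f"bootstrap/bs{b}", gt.replicate_tensor[:, s, b].astype("<f8"))


def _write_rsem_sample(gt: GroundTruth, s: int, rsem_dir: Path, sample: str) -> None:
    n_tx = len(gt.transcript_ids)
    total = gt.true_counts[:, s].sum()
    genes = gt.genes
    gene_tpm = {g: 0.0 for g in genes}
    for t in range(n_tx):
        gene_tpm[gt.gene_ids[t]] += gt.tpm[t, s]

    def fpkm(count: float, eff: float) -> float:
        return 0.0 if total == 0 else count / eff / total * 1e9

    _write_tsv(
        rsem_dir / f"{sample}.isoforms.results",
        ["transcript_id", "gene_id", "length", "effective_length",
         "expected_count", "TPM", "FPKM", "IsoPct"],
        (
            [
                gt.transcript_ids[t],
                gt.gene_ids[t],
                "%d" % gt.lengths[t],
                _f(gt.effective_lengths[t, s]),
                _f(gt.true_counts[t, s]),
                _f(gt.tpm[t, s]),
                _f(fpkm(gt.true_counts[t, s], gt.effective_lengths[t, s])),
                _f(
                    0.0
                    if gene_tpm[gt.gene_ids[t]] == 0
                    else 100.0 * gt.tpm[t, s] / gene_tpm[gt.gene_ids[t]]
                ),
            ]
            for t in range(n_tx)
        ),
    )
    # gene-level table: plain summarization of the same ground truth
    gene_rows = []
    for g in genes:
        members = [t for t in range(n_tx) if gt.gene_ids[t] == g]
        count = sum(gt.true_counts[t, s] for t in members)
        tpm_g = sum(gt.tpm[t, s] for t in members)
        wsum = sum(gt.tpm[t, s] * gt.effective_lengths[t, s] for t in members)
        if tpm_g > 0:
            eff = wsum / tpm_g
            plain = sum(gt.tpm[t, s] * gt.lengths[t] for t in members) / tpm_g
        else:
            eff = sum(gt.effective_lengths[t].mean() for t in members) / len(members)
            plain = sum(gt.lengths[t] for t in members) / len(members)
        gene_rows.append(
            [
                g,
                ",".join(gt.transcript_ids[t] for t in members),
                _f(plain),
                _f(eff),
                _f(count),
                _f(tpm_g),
                _f(fpkm(count, eff) if eff > 0 else 0.0),
            ]
        )
    _write_tsv(
        rsem_dir / f"{sample}.genes.results",
        ["gene_id", "transcript_id(s)", "length", "effective_length",
         "expected_count", "TPM", "FPKM"],
        gene_rows,
    )


def _write_gtf(gt: GroundTruth, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["#!genome synthetic toy annotation"]
    pos = 1000
    genes = gt.genes
    for g_idx, g in enumerate(genes):
        members = [t for t in range(len(gt.transcript_ids)) if gt.gene_ids[t] == g]
        biotype = gt.biotypes[members[0]]
        span = int(max(gt.lengths[t] for t in members)) + 500
        attrs = f'gene_id "{g}"; gene_name "{g}-name"; gene_biotype "{biotype}";'
        lines.append(
            f"chr1\tsynthetic\tgene\t{pos}\t{pos + span}\t.\t+\t.\t{attrs}"
        )
        for t in members:
            t_attrs = (
                f'gene_id "{g}"; transcript_id "{gt.transcript_ids[t]}"; '
                f'gene_name "{g}-name"; gene_biotype "{biotype}";'
            )
            end = pos + int(gt.lengths[t])
            lines.append(f"chr1\tsynthetic\ttranscript\t{pos}\t{end}\t.\t+\t.\t{t_attrs}")
            lines.append(f"chr1\tsynthetic\texon\t{pos}\t{end}\t.\t+\t.\t{t_attrs}")
        pos += span + 1000
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# independent naive oracle


def oracle_summarize(gt: GroundTruth, mode: str = "no", level: str = "gene"):
    """Reference gene-level (or transcript-level) matrices via explicit loops.

    Returns ``(feature_ids, counts, abundance, length)`` as plain numpy
    arrays.  Intentionally naive and loop-based; shares no code with the
    main implementation.
    """
    mode = str(mode).lower()
    n_tx = len(gt.transcript_ids)
    n_s = len(gt.sample_ids)
    genes = gt.genes
    members = {g: [t for t in range(n_tx) if gt.gene_ids[t] == g] for g in genes}

    if level == "gene":
        n_g = len(genes)
        counts = np.zeros((n_g, n_s))
        abundance = np.zeros((n_g, n_s))
        length = np.zeros((n_g, n_s))
        for gi, g in enumerate(genes):
            for s in range(n_s):
                c = a = wl = 0.0
                for t in members[g]:
                    c += gt.true_counts[t, s]
                    a += gt.tpm[t, s]
                    wl += gt.tpm[t, s] * gt.effective_lengths[t, s]
                counts[gi, s] = c
                abundance[gi, s] = a
                if a > 0:
                    length[gi, s] = wl / a
                else:
                    acc = 0.0
                    for t in members[g]:
                        acc += sum(gt.effective_lengths[t, :]) / n_s
                    length[gi, s] = acc / len(members[g])
        feature_ids = list(genes)
    elif level == "transcript":
        counts = gt.true_counts.copy()
        abundance = gt.tpm.copy()
        length = gt.effective_lengths.copy()
        feature_ids = list(gt.transcript_ids)
    else:  # pragma: no cover
        raise UsageError(f"unknown level {level!r}")

    if mode == "no":
        return feature_ids, counts, abundance, length

    n_f = len(feature_ids)
    lib = [sum(counts[i, s] for i in range(n_f)) for s in range(n_s)]
    factor = np.zeros(n_f)
    if mode == "scaled_tpm":
        factor[:] = 1.0
    elif mode == "length_scaled_tpm":
        for i in range(n_f):
            factor[i] = sum(length[i, :]) / n_s
    elif mode == "dtu_scaled_tpm":
        if level != "transcript":
            raise UsageError("dtu_scaled_tpm is transcript-level only")
        for gi, g in enumerate(genes):
            means = sorted(sum(length[t, :]) / n_s for t in members[g])
            k = len(means)
            med = means[k // 2] if k % 2 == 1 else 0.5 * (means[k // 2 - 1] + means[k // 2])
            for t in members[g]:
                factor[t] = med
    else:
        raise UsageError(f"unknown mode {mode!r}")

    new_counts = np.zeros((n_f, n_s))
    for s in range(n_s):
        colsum = sum(abundance[i, s] * factor[i] for i in range(n_f))
        if colsum > 0:
            for i in range(n_f):
                new_counts[i, s] = abundance[i, s] * factor[i] * lib[s] / colsum
    return feature_ids, new_counts, abundance, length


def oracle_summarize_replicates(gt: GroundTruth) -> np.ndarray:
    """Per-gene replicate sums via explicit loops (gene x sample x replicate)."""
    if gt.replicate_tensor is None:
        raise UsageError("ground truth has no replicate tensor")
    genes = gt.genes
    n_g, n_s, n_b = len(genes), len(gt.sample_ids), gt.replicate_tensor.shape[2]
    out = np.zeros((n_g, n_s, n_b))
    for gi, g in enumerate(genes):
        for t in range(len(gt.transcript_ids)):
            if gt.gene_ids[t] == g:
                for s in range(n_s):
                    for b in range(n_b):
                        out[gi, s, b] += gt.replicate_tensor[t, s, b]
    return out
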