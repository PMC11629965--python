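"""Gene-level summarization of transcript estimates.

The core algorithm: transcript counts and TPM abundances are summed per
gene, and the gene effective length is the abundance-weighted mean of the
constituent transcripts' effective lengths,

    L[g, s] = sum_{t in g} a[t, s] * l[t, s] / sum_{t in g} a[t, s],

computed per sample.  When a gene has zero total abundance in a sample the
weighted mean is undefined; the fallback is the mean over the gene's
transcripts of each transcript's cross-sample mean effective length, which
stays within the transcript length range.  Optionally the gene count
matrix is then replaced by one of the counts-from-abundance
bias-correction modes (see :mod:`txsum.counts_transform`).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import infreps
from .counts_transform import CountsFromAbundanceMode, apply_mode
from .errors import DataError, UsageError
from .quant_io import TranscriptQuant
from .txgene_map import TranscriptGeneMap

logger = logging.getLogger(__name__)


@dataclass
class QuantDataset:
    """Multi-sample feature x sample container.

    Holds three aligned matrices (counts, abundance, length), an optional
    inferential-replicate tensor, and per-feature annotations.  ``level``
    is ``"transcript"`` or ``"gene"``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    abundance: np.ndarray
    length: np.ndarray
    level: str = "transcript"
    replicates: infreps.InferentialReplicates | None = None
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        shape = (len(self.feature_ids), len(self.sample_ids))
        for name in ("counts", "abundance", "length"):
            mat = np.asarray(getattr(self, name), dtype=np.float64)
            if mat.shape != shape:
                raise DataError(f"{name} matrix has shape {mat.shape}, expected {shape}")
            setattr(self, name, mat)
        if self.level not in ("transcript", "gene"):
            raise UsageError(f"level must be 'transcript' or 'gene', got {self.level!r}")
        if self.level == "gene" and len(set(self.feature_ids)) != len(self.feature_ids):
            raise DataError("gene-level feature ids must be unique")
        if self.replicates is not None and self.replicates.tensor.shape[:2] != shape:
            raise DataError(
                f"replicate tensor shape {self.replicates.tensor.shape[:2]} does not "
                f"match matrices {shape}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def build_dataset(samples: list[TranscriptQuant]) -> QuantDataset:
    """Assemble per-sample tables into one aligned feature x sample dataset.

    Features are ordered as in the first sample; later samples are
    reindexed by transcript id and must expose the identical id set.
    """
    if not samples:
        raise UsageError("build_dataset: at least one sample is required")
    first = samples[0]
    ref_ids = list(first.transcript_ids)
    ref_set = set(ref_ids)
    n, m = len(ref_ids), len(samples)
    counts = np.empty((n, m))
    abundance = np.empty((n, m))
    length = np.empty((n, m))
    rep_blocks: list[np.ndarray | None] = []
    for j, sample in enumerate(samples):
        if list(sample.transcript_ids) != ref_ids:
            sample_set = set(sample.transcript_ids)
            if sample_set != ref_set:
                diff = sorted((ref_set ^ sample_set))[:10]
                raise DataError(
                    f"sample {sample.sample_id!r} disagrees with "
                    f"{first.sample_id!r} on the transcript id set; differing ids: "
                    + ", ".join(diff)
                )
            order = {t: i for i, t in enumerate(sample.transcript_ids)}
            idx = np.array([order[t] for t in ref_ids])
        else:
            idx = slice(None)
        counts[:, j] = sample.counts[idx]
        abundance[:, j] = sample.abundance[idx]
        length[:, j] = sample.effective_length[idx]
        rep_blocks.append(sample.replicates[idx] if sample.replicates is not None else None)

    replicates = None
    if any(b is not None for b in rep_blocks):
        if any(b is None for b in rep_blocks):
            missing = [s.sample_id for s, b in zip(samples, rep_blocks) if b is None]
            raise DataError(
                "inferential replicates present for some samples but missing for: "
                + ", ".join(missing)
            )
        n_reps = {b.shape[1] for b in rep_blocks}
        if len(n_reps) != 1:
            raise DataError(f"samples carry differing replicate counts: {sorted(n_reps)}")
        tensor = np.stack(rep_blocks, axis=1)  # feature x sample x replicate
        kinds = {s.replicate_kind for s in samples}
        kind = kinds.pop() if len(kinds) == 1 else "unknown"
        replicates = infreps.InferentialReplicates(tensor=tensor, kind=kind)

    meta = None
    if first.gene_ids is not None:
        meta = pd.DataFrame({"gene_id": first.gene_ids}, index=pd.RangeIndex(n))
    level = "gene" if first.already_summarized else "transcript"
    return QuantDataset(
        feature_ids=ref_ids,
        sample_ids=[s.sample_id for s in samples],
        counts=counts,
        abundance=abundance,
        length=length,
        level=level,
        replicates=replicates,
        feature_meta=meta,
    )


def _gene_codes(
    feature_ids: list[str], mapping: TranscriptGeneMap | dict[str, str], drop_unmapped: bool
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Map features to gene codes in first-appearance order.

    Returns (codes, gene_ids, kept_mask); unmapped features are an error
    unless ``drop_unmapped``.
    """
    gene_of = mapping if isinstance(mapping, dict) else mapping.gene_of()
    unmapped = [t for t in feature_ids if t not in gene_of]
    if unmapped:
        if not drop_unmapped:
            shown = ", ".join(unmapped[:10])
            raise DataError(
                f"{len(unmapped)} transcript(s) absent from the transcript-to-gene "
                f"mapping: {shown}" + (" ..." if len(unmapped) > 10 else "")
                + " (pass drop_unmapped to discard them)"
            )
        logger.warning("dropping %d unmapped transcripts", len(unmapped))
    kept = np.array([t in gene_of for t in feature_ids], dtype=bool)
    assigned = [gene_of[t] for t, k in zip(feature_ids, kept) if k]
    codes, genes = pd.factorize(np.asarray(assigned, dtype=object))
    return codes, [str(g) for g in genes], kept


def _group_sum(matrix: np.ndarray, codes: np.ndarray, n_genes: int) -> np.ndarray:
    out = np.zeros((n_genes,) + matrix.shape[1:], dtype=np.float64)
    np.add.at(out, codes, matrix)
    return out


def gene_lengths(
    abundance: np.ndarray,
    length: np.ndarray,
    codes: np.ndarray,
    n_genes: int,
) -> np.ndarray:
    """Abundance-weighted mean effective length per gene and sample.

    ``codes`` assigns each transcript row to a gene index.  Where a gene's
    total abundance in a sample is zero, the entry falls back to the mean
    over that gene's transcripts of their cross-sample mean lengths.
    """
    weighted = _group_sum(abundance * length, codes, n_genes)
    weights = _group_sum(abundance, codes, n_genes)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = weighted / weights
    # single-transcript genes reproduce their transcript row exactly
    # (a one-element weighted mean must not pick up rounding from a*l/a)
    sizes = np.bincount(codes, minlength=n_genes)
    single = sizes[codes] == 1
    if np.any(single):
        out[codes[single]] = length[single]
    if np.any(weights == 0):
        tx_mean = length.mean(axis=1)  # cross-sample mean per transcript
        fallback = _group_sum(tx_mean, codes, n_genes) / np.bincount(codes, minlength=n_genes)
        rows, cols = np.nonzero(weights == 0)
        out[rows, cols] = fallback[rows]
    return out


def summarize_to_gene(
    ds: QuantDataset,
    mapping: TranscriptGeneMap | dict[str, str],
    mode: CountsFromAbundanceMode | str = CountsFromAbundanceMode.NO,
    drop_unmapped: bool = False,
) -> QuantDataset:
    """Summarize a transcript-level dataset to gene level.

    Gene counts and abundances are column-wise sums over each gene's
    transcripts; gene lengths come from :func:`gene_lengths`.  With a
    counts-from-abundance mode other than ``no``, the gene count matrix is
    then recomputed from the gene-level abundance and length matrices,
    rescaled to the original per-sample library sizes.  Gene order is the
    first-appearance order of genes along the transcript feature axis.
    Inferential replicates, when present, are summed per gene as raw
    counts (no mode transform) and their per-entry variance is recomputed.

    An already gene-level dataset (e.g. RSEM gene input) passes through
    unchanged with a logged notice.
    """
    mode = CountsFromAbundanceMode.from_any(mode)
    if ds.level == "gene":
        logger.info("dataset is already gene-level; summarization is a pass-through")
        return ds
    if mode is CountsFromAbundanceMode.DTU_SCALED_TPM:
        raise UsageError(
            "dtu_scaled_tpm is a transcript-level mode; it cannot be combined "
            "with gene-level summarization"
        )
    codes, genes, kept = _gene_codes(ds.feature_ids, mapping, drop_unmapped)
    counts = ds.counts[kept]
    abundance = ds.abundance[kept]
    length = ds.length[kept]
    n_genes = len(genes)
    gene_counts = _group_sum(counts, codes, n_genes)
    gene_abundance = _group_sum(abundance, codes, n_genes)
    gene_length = gene_lengths(abundance, length, codes, n_genes)
    if mode is not CountsFromAbundanceMode.NO:
        gene_counts = apply_mode(gene_counts, gene_abundance, gene_length, mode)

    replicates = None
    if ds.replicates is not None:
        kept_reps = dataclasses.replace(
            ds.replicates, tensor=ds.replicates.tensor[kept], variance=None
        )
        replicates = infreps.summarize_replicates(kept_reps, codes, n_genes)
        replicates.variance = infreps.replicate_variance(replicates)

    meta = _gene_meta(ds, mapping, kept, codes, genes)
    return QuantDataset(
        feature_ids=genes,
        sample_ids=list(ds.sample_ids),
        counts=gene_counts,
        abundance=gene_abundance,
        length=gene_length,
        level="gene",
        replicates=replicates,
        feature_meta=meta,
    )


def _gene_meta(ds, mapping, kept, codes, genes) -> pd.DataFrame:
    meta = pd.DataFrame({"gene_id": genes})
    if isinstance(mapping, TranscriptGeneMap):
        kept_tx = [t for t, k in zip(ds.feature_ids, kept) if k]
        names = mapping.name_of()
        biotypes = mapping.biotype_of()
        if names:
            first: dict[int, str] = {}
            for t, c in zip(kept_tx, codes):
                if c not in first and t in names:
                    first[int(c)] = names[t]
            meta["gene_name"] = [first.get(i) for i in range(len(genes))]
        if biotypes:
            first = {}
            for t, c in zip(kept_tx, codes):
                if c not in first and t in biotypes:
                    first[int(c)] = biotypes[t]
            meta["biotype"] = [first.get(i) for i in range(len(genes))]
    return meta


def transcript_dataset_with_mode(
    ds: QuantDataset,
    mode: CountsFromAbundanceMode | str,
    mapping: TranscriptGeneMap | dict[str, str] | None = None,
    drop_unmapped: bool = False,
) -> QuantDataset:
    """Transcript-level output with a counts-from-abundance transform.

    Applies the requested mode to the transcript count matrix in place of
    summarization (``dtu_scaled_tpm`` needs the transcript-to-gene mapping
    for its per-gene median length).  Feature annotations from the mapping
    are attached when available.
    """
    mode = CountsFromAbundanceMode.from_any(mode)
    if ds.level != "transcript":
        raise UsageError("transcript-level output requires a transcript-level dataset")
    gene_assignment = None
    meta = ds.feature_meta
    if mapping is not None:
        codes, genes, kept = _gene_codes(ds.feature_ids, mapping, drop_unmapped)
        if not kept.all():
            ds = dataclasses.replace(
                ds,
                feature_ids=[t for t, k in zip(ds.feature_ids, kept) if k],
                counts=ds.counts[kept],
                abundance=ds.abundance[kept],
                length=ds.length[kept],
                replicates=dataclasses.replace(
                    ds.replicates, tensor=ds.replicates.tensor[kept], variance=None
                )
                if ds.replicates is not None
                else None,
                feature_meta=meta.loc[kept].reset_index(drop=True) if meta is not None else None,
            )
        gene_assignment = (codes, len(genes))
        gene_of = mapping if isinstance(mapping, dict) else mapping.gene_of()
        meta = pd.DataFrame({"gene_id": [gene_of[t] for t in ds.feature_ids]})
        if isinstance(mapping, TranscriptGeneMap):
            names, biotypes = mapping.name_of(), mapping.biotype_of()
            if names:
                meta["gene_name"] = [names.get(t) for t in ds.feature_ids]
            if biotypes:
                meta["biotype"] = [biotypes.get(t) for t in ds.feature_ids]
    if mode is CountsFromAbundanceMode.DTU_SCALED_TPM and gene_assignment is None:
        raise UsageError("dtu_scaled_tpm requires a transcript-to-gene mapping")
    counts = apply_mode(ds.counts, ds.abundance, ds.length, mode, groups=gene_assignment)
    return dataclasses.replace(ds, counts=counts, feature_meta=meta)
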