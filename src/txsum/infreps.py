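"""Inferential replicates (bootstrap / Gibbs) through summarization.

Quantifiers resolve read-to-transcript ambiguity probabilistically, so the
estimated counts carry inferential uncertainty.  Bootstrap or Gibbs
resamples of the quantifier's posterior are carried here as a
feature x sample x replicate tensor; gene-level summarization sums each
replicate slice per gene exactly as it sums the count matrix, and the
per-entry unbiased sample variance across replicates is exposed for
downstream uncertainty-aware tools.

Counts-from-abundance transforms are deliberately not applied to
replicate tensors: replicates carry raw summed counts only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, UsageError

REPLICATE_KINDS = ("bootstrap", "gibbs", "unknown")


@dataclass
class InferentialReplicates:
    """Replicate-count tensor with derived per-entry variance.

    ``tensor`` is feature x sample x replicate, non-negative.
    """

    tensor: np.ndarray
    kind: str = "unknown"
    variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        if self.tensor.ndim != 3:
            raise DataError(
                f"replicate tensor must be feature x sample x replicate, got "
                f"{self.tensor.ndim} dimensions"
            )
        if np.any(self.tensor < 0):
            raise DataError("replicate tensor contains negative values")
        if self.kind not in REPLICATE_KINDS:
            raise DataError(f"unknown replicate kind {self.kind!r}")
        if self.variance is not None:
            self.variance = np.asarray(self.variance, dtype=np.float64)
            if self.variance.shape != self.tensor.shape[:2]:
                raise DataError("variance shape does not match the feature x sample axes")
            if np.any(self.variance < 0):
                raise DataError("variance must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.tensor.shape[2]


def summarize_replicates(
    reps: InferentialReplicates, codes: np.ndarray, n_genes: int
) -> InferentialReplicates:
    """Sum each replicate slice per gene.

    ``codes`` assigns each transcript row of the tensor to a gene index,
    exactly as for the count matrix; the replicate kind is preserved.
    """
    codes = np.asarray(codes)
    if codes.shape != (reps.tensor.shape[0],):
        raise DataError(
            f"gene assignment covers {codes.shape[0] if codes.ndim else 0} features "
            f"but the replicate tensor has {reps.tensor.shape[0]}"
        )
    out = np.zeros((n_genes,) + reps.tensor.shape[1:])
    np.add.at(out, codes, reps.tensor)
    return InferentialReplicates(tensor=out, kind=reps.kind)


def replicate_variance(reps: InferentialReplicates) -> np.ndarray:
    """Unbiased sample variance (divisor n-1) across the replicate axis."""
    if reps.n_replicates < 2:
        raise UsageError(
            f"variance requires at least 2 replicates, got {reps.n_replicates}"
        )
    return np.var(reps.tensor, axis=2, ddof=1)
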