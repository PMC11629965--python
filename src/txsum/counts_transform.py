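"""Counts-from-abundance bias-correction modes.

Estimated counts are biased by effective length and by shifts in isoform
usage between samples.  The correction replaces counts with pseudo-counts
derived from the TPM abundance matrix, rescaled per sample so that column
sums match the original library sizes:

* ``scaled_tpm`` — pseudo-counts proportional to TPM.
* ``length_scaled_tpm`` — TPM multiplied by each feature's cross-sample
  mean effective length before rescaling (restores a length-proportional
  count scale while keeping abundance-derived proportions).
* ``dtu_scaled_tpm`` — TPM multiplied by the median, over the feature's
  gene's transcripts, of their cross-sample mean lengths; transcript-level
  only, intended for differential transcript usage analysis where counts
  of isoforms of one gene must share a common length factor.
* ``no`` — the estimated counts are kept as-is.

Library size (a sample's total estimated read count) is the conserved
quantity: for every mode the transformed column sums equal the original
count column sums.
"""

from __future__ import annotations

import enum
import logging

import numpy as np

from .errors import UsageError

logger = logging.getLogger(__name__)


class CountsFromAbundanceMode(enum.Enum):
    """The four counts-from-abundance modes."""

    NO = "no"
    SCALED_TPM = "scaled_tpm"
    LENGTH_SCALED_TPM = "length_scaled_tpm"
    DTU_SCALED_TPM = "dtu_scaled_tpm"

    @classmethod
    def from_any(cls, value: "CountsFromAbundanceMode | str") -> "CountsFromAbundanceMode":
        """Accept enum members, snake_case strings, or camelCase aliases."""
        if isinstance(value, cls):
            return value
        aliases = {
            "scaledtpm": cls.SCALED_TPM,
            "lengthscaledtpm": cls.LENGTH_SCALED_TPM,
            "dtuscaledtpm": cls.DTU_SCALED_TPM,
            "none": cls.NO,
        }
        key = str(value).strip().lower()
        try:
            return cls(key)
        except ValueError:
            pass
        normalized = key.replace("_", "").replace("-", "")
        if normalized in aliases:
            return aliases[normalized]
        raise UsageError(
            f"unknown counts-from-abundance mode {value!r}; expected one of "
            + ", ".join(m.value for m in cls)
        )


def library_sizes(counts: np.ndarray) -> np.ndarray:
    """Per-sample library sizes: column sums of the original count matrix."""
    counts = np.asarray(counts, dtype=np.float64)
    return counts.sum(axis=0)


def _rescale_to_library(x: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    colsums = x.sum(axis=0)
    zero = colsums == 0
    if np.any(zero & (lib_sizes > 0)):
        logger.warning(
            "%d sample(s) have zero total abundance; their transformed count "
            "columns are set to zero",
            int((zero & (lib_sizes > 0)).sum()),
        )
    # normalize to per-column proportions first: x / colsum is bounded by 1,
    # so subnormal column sums cannot overflow the rescale
    safe = np.where(zero, 1.0, colsums)
    return (x / safe) * np.where(zero, 0.0, lib_sizes)


def apply_mode(
    counts: np.ndarray,
    abundance: np.ndarray,
    length: np.ndarray,
    mode: "CountsFromAbundanceMode | str",
    groups: tuple[np.ndarray, int] | None = None,
) -> np.ndarray:
    """Transform a count matrix per the requested counts-from-abundance mode.

    ``groups``, required only for ``dtu_scaled_tpm``, is a pair
    ``(codes, n_genes)`` assigning each feature row to a gene index.
    Matrices are feature x sample.  Returns a new count matrix whose
    column sums equal those of the input ``counts``.
    """
    mode = CountsFromAbundanceMode.from_any(mode)
    counts = np.asarray(counts, dtype=np.float64)
    abundance = np.asarray(abundance, dtype=np.float64)
    length = np.asarray(length, dtype=np.float64)
    if mode is CountsFromAbundanceMode.NO:
        return counts
    if not (counts.shape == abundance.shape == length.shape):
        raise UsageError("apply_mode: counts, abundance, and length shapes differ")
    lib = library_sizes(counts)
    if mode is CountsFromAbundanceMode.SCALED_TPM:
        return _rescale_to_library(abundance.copy(), lib)
    mean_length = length.mean(axis=1)
    if mode is CountsFromAbundanceMode.LENGTH_SCALED_TPM:
        return _rescale_to_library(abundance * mean_length[:, None], lib)
    # dtu_scaled_tpm: median over each gene's transcripts of their
    # cross-sample mean lengths; output stays transcript-level.
    if groups is None:
        raise UsageError("dtu_scaled_tpm requires a transcript-to-gene assignment")
    codes, n_genes = groups
    codes = np.asarray(codes)
    if codes.shape != (counts.shape[0],):
        raise UsageError(
            f"apply_mode: gene assignment length {codes.shape} does not match "
            f"{counts.shape[0]} features"
        )
    median_by_gene = np.empty(n_genes)
    for g in range(n_genes):
        members = mean_length[codes == g]
        if members.size == 0:
            raise UsageError(f"apply_mode: gene index {g} has no transcripts")
        median_by_gene[g] = np.median(members)
    return _rescale_to_library(abundance * median_by_gene[codes][:, None], lib)
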