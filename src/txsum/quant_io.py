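"""Readers for per-sample transcript quantification files.

Supported dialects: Salmon/Sailfish ``quant.sf`` (with optional bootstrap
or Gibbs inferential replicates under ``aux_info/``), kallisto
``abundance.tsv`` / ``abundance.h5``, RSEM ``*.isoforms.results`` and
``*.genes.results``, and a user-configurable generic tab-separated format
through which piscem-infer and oarfish output is also handled.

Every reader returns a :class:`TranscriptQuant`, a single sample's
transcript table holding ids, effective lengths, estimated counts and TPM
abundances in file row order.  Cross-sample alignment happens later, in
:func:`txsum.summarize.build_dataset`.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, UsageError

logger = logging.getLogger(__name__)

SOURCE_FORMATS = (
    "salmon",
    "sailfish",
    "kallisto",
    "rsem_isoform",
    "rsem_gene",
    "piscem",
    "oarfish",
    "generic_tsv",
)

SALMON_COLUMNS = ("Name", "Length", "EffectiveLength", "TPM", "NumReads")
KALLISTO_COLUMNS = ("target_id", "length", "eff_length", "est_counts", "tpm")
RSEM_ISOFORM_COLUMNS = ("transcript_id", "gene_id", "effective_length", "expected_count", "TPM")
RSEM_GENE_COLUMNS = ("gene_id", "effective_length", "expected_count", "TPM")


@dataclass(frozen=True)
class ColumnMap:
    """Names of the columns carrying each quantity in a generic TSV.

    ``abundance_column`` may be ``None``; the TPM abundance is then derived
    from counts and effective lengths via :func:`derive_tpm`.
    """

    id_column: str
    counts_column: str
    length_column: str
    abundance_column: str | None = None


#: Preset column maps for tools whose output is a plain TSV with fixed
#: headers; they go through :func:`read_generic_tsv` rather than a
#: bespoke parser.
DIALECTS: dict[str, ColumnMap] = {
    "oarfish": ColumnMap(id_column="tname", counts_column="num_reads", length_column="len"),
    "piscem": ColumnMap(id_column="target_name", counts_column="ecount", length_column="eeln"),
}


@dataclass
class TranscriptQuant:
    """One sample's transcript-level quantification.

    All vectors are aligned to ``transcript_ids`` and follow the row order
    of the source file.  ``replicates`` (when present) is a transcripts x
    n_replicates array of inferential-replicate counts.
    """

    sample_id: str
    transcript_ids: list[str]
    effective_length: np.ndarray
    counts: np.ndarray
    abundance: np.ndarray
    source_format: str = "generic_tsv"
    replicates: np.ndarray | None = None
    replicate_kind: str = "unknown"
    gene_ids: list[str] | None = None
    already_summarized: bool = False

    def __post_init__(self) -> None:
        self.effective_length = np.asarray(self.effective_length, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.abundance = np.asarray(self.abundance, dtype=np.float64)
        n = len(self.transcript_ids)
        for name in ("effective_length", "counts", "abundance"):
            vec = getattr(self, name)
            if vec.shape != (n,):
                raise DataError(
                    f"sample {self.sample_id!r}: {name} has length {vec.shape}, "
                    f"expected ({n},) to match transcript_ids"
                )
        if len(set(self.transcript_ids)) != n:
            seen: set[str] = set()
            dup = next(t for t in self.transcript_ids if t in seen or seen.add(t))
            raise DataError(
                f"sample {self.sample_id!r}: duplicate transcript id {dup!r}"
            )
        if np.any(self.counts < 0) or np.any(self.abundance < 0):
            raise DataError(f"sample {self.sample_id!r}: negative counts or abundance")
        # Degenerate effective lengths: zero length with zero count is
        # tolerated (coerced to 1 for safe division); zero length with
        # positive signal is an error.
        nonpos = self.effective_length <= 0
        if np.any(nonpos):
            active = nonpos & ((self.counts > 0) | (self.abundance > 0))
            if np.any(active):
                bad = self.transcript_ids[int(np.argmax(active))]
                raise DataError(
                    f"sample {self.sample_id!r}: transcript {bad!r} has "
                    "non-positive effective length but positive counts/abundance"
                )
            logger.warning(
                "sample %r: %d transcripts with non-positive effective length "
                "and zero counts; coercing length to 1",
                self.sample_id,
                int(nonpos.sum()),
            )
            self.effective_length = np.where(nonpos, 1.0, self.effective_length)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def normalized(self, ignore_version: bool = False, ignore_after_bar: bool = False) -> "TranscriptQuant":
        """Return a copy with identifiers normalized (see ``normalize_id``)."""
        from .txgene_map import normalize_id

        if not (ignore_version or ignore_after_bar):
            return self
        ids = [normalize_id(t, ignore_version, ignore_after_bar) for t in self.transcript_ids]
        out = replace(self, transcript_ids=ids)
        return out


def derive_tpm(counts: np.ndarray, effective_length: np.ndarray) -> np.ndarray:
    """Transcripts-per-million abundance from counts and effective lengths.

    TPM_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6.  An all-zero count
    vector yields an all-zero abundance vector.
    """
    counts = np.asarray(counts, dtype=np.float64)
    length = np.asarray(effective_length, dtype=np.float64)
    if np.any(counts < 0) or np.any(length < 0):
        raise DataError("derive_tpm: negative counts or lengths")
    if np.any((length == 0) & (counts > 0)):
        raise DataError("derive_tpm: zero effective length with positive count")
    safe_length = np.where(length > 0, length, 1.0)
    rate = counts / safe_length
    total = rate.sum()
    if total == 0:
        return np.zeros_like(counts)
    return rate / total * 1e6


def _read_table(path: Path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited text table tolerating CRLF endings and blank lines."""
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as {sep!r}-separated table: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, required, path: Path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")


def _numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    raw = df[col]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.any():
        row = int(np.argmax(bad.to_numpy())) + 2  # +1 header, +1 one-based
        raise FormatError(
            f"{path}: non-numeric value {raw[bad].iloc[0]!r} in column {col!r} (line {row})"
        )
    if values.isna().any():
        row = int(np.argmax(values.isna().to_numpy())) + 2
        raise FormatError(f"{path}: empty value in column {col!r} (line {row})")
    return values.to_numpy(dtype=np.float64)


# ---------------------------------------------------------------------------
# Salmon / Sailfish


def _salmon_meta_info(sample_dir: Path) -> dict | None:
    for candidate in (sample_dir / "aux_info" / "meta_info.json", sample_dir / "meta_info.json"):
        if candidate.is_file():
            with open(candidate) as fh:
                return json.load(fh)
    return None


def _read_salmon_replicates(sample_dir: Path, n_transcripts: int) -> tuple[np.ndarray, str] | None:
    """Decode inferential replicates from ``aux_info/bootstrap/bootstraps.gz``.

    The payload is a flat little-endian float64 array, replicate-major
    (replicate x transcript); the replicate count comes from
    ``meta_info.json`` (``num_bootstraps``).  Gibbs samples use the same
    layout, distinguished by the ``samp_type`` field.
    """
    boot_path = sample_dir / "aux_info" / "bootstrap" / "bootstraps.gz"
    if not boot_path.is_file():
        return None
    meta = _salmon_meta_info(sample_dir)
    if meta is None or "num_bootstraps" not in meta:
        raise FormatError(
            f"{sample_dir}: bootstrap data present but no meta_info.json with 'num_bootstraps'"
        )
    n_reps = int(meta["num_bootstraps"])
    if n_reps <= 0:
        return None
    with gzip.open(boot_path, "rb") as fh:
        payload = fh.read()
    flat = np.frombuffer(payload, dtype="<f8")
    if flat.size != n_reps * n_transcripts:
        raise FormatError(
            f"{boot_path}: expected {n_reps} x {n_transcripts} values, found {flat.size}"
        )
    tensor = flat.reshape(n_reps, n_transcripts).T.copy()
    kind = "gibbs" if str(meta.get("samp_type", "")).lower() == "gibbs" else "bootstrap"
    return tensor, kind


def read_salmon(
    sample_dir_or_file: str | Path,
    with_inferential: bool = False,
    sample_id: str | None = None,
    source_format: str = "salmon",
) -> TranscriptQuant:
    """Parse a Salmon/Sailfish ``quant.sf`` file or sample directory.

    When ``with_inferential`` is set and the sample directory carries an
    ``aux_info`` bootstrap block, the replicate matrix is attached to the
    returned :class:`TranscriptQuant`.
    """
    path = Path(sample_dir_or_file)
    if path.is_dir():
        sample_dir, quant_path = path, path / "quant.sf"
        if not quant_path.is_file():
            raise FormatError(f"{path}: directory contains no quant.sf")
    else:
        sample_dir, quant_path = path.parent, path
    df = _read_table(quant_path)
    _require_columns(df, SALMON_COLUMNS, quant_path)
    quant = TranscriptQuant(
        sample_id=sample_id or sample_dir.name,
        transcript_ids=df["Name"].astype(str).tolist(),
        effective_length=_numeric(df, "EffectiveLength", quant_path),
        counts=_numeric(df, "NumReads", quant_path),
        abundance=_numeric(df, "TPM", quant_path),
        source_format=source_format,
    )
    if with_inferential:
        decoded = _read_salmon_replicates(sample_dir, quant.n_transcripts)
        if decoded is None:
            raise DataError(f"{sample_dir}: no inferential replicates found")
        quant.replicates, quant.replicate_kind = decoded
    return quant


# ---------------------------------------------------------------------------
# kallisto

KALLISTO_H5_DATASETS = ("aux/ids", "aux/eff_lengths", "est_counts")


def _read_kallisto_tsv(path: Path, sample_id: str) -> TranscriptQuant:
    df = _read_table(path)
    _require_columns(df, KALLISTO_COLUMNS, path)
    return TranscriptQuant(
        sample_id=sample_id,
        transcript_ids=df["target_id"].astype(str).tolist(),
        effective_length=_numeric(df, "eff_length", path),
        counts=_numeric(df, "est_counts", path),
        abundance=_numeric(df, "tpm", path),
        source_format="kallisto",
    )


def _read_kallisto_h5(path: Path, sample_id: str, with_inferential: bool) -> TranscriptQuant:
    import h5py

    with h5py.File(path, "r") as h5:
        for name in KALLISTO_H5_DATASETS:
            if name not in h5:
                raise FormatError(f"{path}: missing HDF5 dataset {name!r}")
        ids = [i.decode() if isinstance(i, bytes) else str(i) for i in h5["aux/ids"][()]]
        eff_length = np.asarray(h5["aux/eff_lengths"][()], dtype=np.float64)
        counts = np.asarray(h5["est_counts"][()], dtype=np.float64)
        replicates = None
        if with_inferential:
            if "bootstrap" not in h5:
                raise DataError(f"{path}: no inferential replicates found")
            group = h5["bootstrap"]
            slices = []
            for i in range(len(group)):
                name = f"bs{i}"
                if name not in group:
                    raise FormatError(f"{path}: missing HDF5 dataset 'bootstrap/{name}'")
                slices.append(np.asarray(group[name][()], dtype=np.float64))
            replicates = np.stack(slices, axis=1) if slices else None
            if replicates is None:
                raise DataError(f"{path}: no inferential replicates found")
    quant = TranscriptQuant(
        sample_id=sample_id,
        transcript_ids=ids,
        effective_length=eff_length,
        counts=counts,
        abundance=derive_tpm(counts, eff_length),
        source_format="kallisto",
    )
    quant.replicates = replicates
    if replicates is not None:
        quant.replicate_kind = "bootstrap"
    return quant


def read_kallisto(
    sample_path: str | Path,
    prefer_h5: bool = False,
    with_inferential: bool = False,
    sample_id: str | None = None,
) -> TranscriptQuant:
    """Parse kallisto output (``abundance.tsv`` or ``abundance.h5``).

    When both files exist in a sample directory the TSV wins unless
    ``prefer_h5`` is set; inferential replicates require the HDF5 file.
    """
    path = Path(sample_path)
    if path.is_dir():
        tsv, h5 = path / "abundance.tsv", path / "abundance.h5"
        name = sample_id or path.name
        if with_inferential or prefer_h5:
            if not h5.is_file():
                if with_inferential:
                    raise DataError(f"{path}: no inferential replicates found (abundance.h5 absent)")
                raise FormatError(f"{path}: abundance.h5 not found")
            return _read_kallisto_h5(h5, name, with_inferential)
        if tsv.is_file():
            return _read_kallisto_tsv(tsv, name)
        if h5.is_file():
            return _read_kallisto_h5(h5, name, with_inferential)
        raise FormatError(f"{path}: neither abundance.tsv nor abundance.h5 found")
    name = sample_id or path.parent.name
    if path.suffix in (".h5", ".hdf5"):
        return _read_kallisto_h5(path, name, with_inferential)
    if with_inferential:
        raise DataError(f"{path}: inferential replicates require the HDF5 file")
    return _read_kallisto_tsv(path, name)


# ---------------------------------------------------------------------------
# RSEM


def read_rsem(
    sample_path: str | Path,
    level: str = "isoform",
    sample_id: str | None = None,
) -> TranscriptQuant:
    """Parse RSEM ``*.isoforms.results`` or ``*.genes.results``.

    Isoform-level input retains the embedded ``gene_id`` column so a
    transcript-to-gene mapping can be built from the file itself.
    Gene-level input is flagged as already summarized; gene-level
    summarization then passes it through unchanged.
    """
    if level not in ("isoform", "gene"):
        raise UsageError(f"read_rsem: level must be 'isoform' or 'gene', got {level!r}")
    path = Path(sample_path)
    df = _read_table(path)
    if level == "isoform":
        if "transcript_id" not in df.columns and "gene_id" in df.columns:
            raise DataError(
                f"{path}: looks like a gene-level file (no transcript_id column) "
                "but level='isoform' was requested"
            )
        _require_columns(df, RSEM_ISOFORM_COLUMNS, path)
        return TranscriptQuant(
            sample_id=sample_id or path.stem.replace(".isoforms", ""),
            transcript_ids=df["transcript_id"].astype(str).tolist(),
            effective_length=_numeric(df, "effective_length", path),
            counts=_numeric(df, "expected_count", path),
            abundance=_numeric(df, "TPM", path),
            source_format="rsem_isoform",
            gene_ids=df["gene_id"].astype(str).tolist(),
        )
    if "transcript_id" in df.columns:
        raise DataError(
            f"{path}: looks like an isoform-level file (has transcript_id column) "
            "but level='gene' was requested"
        )
    _require_columns(df, RSEM_GENE_COLUMNS, path)
    return TranscriptQuant(
        sample_id=sample_id or path.stem.replace(".genes", ""),
        transcript_ids=df["gene_id"].astype(str).tolist(),
        effective_length=_numeric(df, "effective_length", path),
        counts=_numeric(df, "expected_count", path),
        abundance=_numeric(df, "TPM", path),
        source_format="rsem_gene",
        already_summarized=True,
    )


# ---------------------------------------------------------------------------
# Generic TSV


def read_generic_tsv(
    path: str | Path,
    columns: ColumnMap,
    sample_id: str | None = None,
    source_format: str = "generic_tsv",
) -> TranscriptQuant:
    """Parse any TSV with named id / counts / effective-length columns.

    When no abundance column is named, TPM is derived from counts and
    effective lengths.
    """
    path = Path(path)
    df = _read_table(path)
    required = [columns.id_column, columns.counts_column, columns.length_column]
    if columns.abundance_column is not None:
        required.append(columns.abundance_column)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    counts = _numeric(df, columns.counts_column, path)
    length = _numeric(df, columns.length_column, path)
    if columns.abundance_column is not None:
        abundance = _numeric(df, columns.abundance_column, path)
    else:
        abundance = derive_tpm(counts, length)
    return TranscriptQuant(
        sample_id=sample_id or path.stem,
        transcript_ids=df[columns.id_column].astype(str).tolist(),
        effective_length=length,
        counts=counts,
        abundance=abundance,
        source_format=source_format,
    )
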