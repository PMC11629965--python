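"""Transcript-to-gene mappings: construction, normalization, biotype filtering.

Gene-level summarization needs a table associating every transcript with a
gene, optionally carrying gene names and biotypes.  Mappings can be built
from a GTF/GFF2 annotation or any delimited table (e.g. a locally saved
BioMart export).  Identifier normalization (version stripping, pipe
truncation) is applied symmetrically to quantification ids and mapping ids
so that reference-release drift does not break the join.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .quant_io import ColumnMap

if TYPE_CHECKING:  # pragma: no cover
    from .summarize import QuantDataset

logger = logging.getLogger(__name__)

#: Attribute keys searched, in order, for a biotype label in GTF records.
BIOTYPE_ATTRIBUTE_ORDER = ("gene_biotype", "transcript_biotype", "gene_type")

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_VERSION_RE = re.compile(r"\.\d+$")


def normalize_id(identifier: str, ignore_version: bool = False, ignore_after_bar: bool = False) -> str:
    """Normalize a transcript/gene identifier.

    ``ignore_after_bar`` truncates at the first ``|`` (applied first, for
    pipe-delimited FASTA headers); ``ignore_version`` strips a trailing
    ``.<digits>`` version suffix.  With both flags off this is the identity.
    """
    if ignore_after_bar:
        identifier = identifier.split("|", 1)[0]
    if ignore_version:
        identifier = _VERSION_RE.sub("", identifier)
    return identifier


@dataclass
class TranscriptGeneMap:
    """Transcript -> gene association with optional names and biotypes.

    Backed by a DataFrame with columns ``transcript_id``, ``gene_id`` and
    optionally ``gene_name`` and ``biotype``.  Transcript ids are unique:
    duplicates with an identical gene assignment are dropped with a
    warning, conflicting duplicates are an error.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        for col in ("transcript_id", "gene_id"):
            if col not in df.columns:
                raise DataError(f"transcript-to-gene table lacks a {col!r} column")
        df = df.copy()
        df["transcript_id"] = df["transcript_id"].astype(str)
        df["gene_id"] = df["gene_id"].astype(str)
        if (df["gene_id"].str.len() == 0).any() or df["gene_id"].isin(["nan", "None"]).any():
            raise DataError("transcript-to-gene table contains empty gene ids")
        dup_mask = df.duplicated(subset="transcript_id", keep=False)
        if dup_mask.any():
            per_tx = df.loc[dup_mask].groupby("transcript_id")["gene_id"].nunique()
            conflicts = per_tx[per_tx > 1]
            if len(conflicts):
                raise DataError(
                    "conflicting gene assignment for transcript(s): "
                    + ", ".join(conflicts.index[:10])
                )
            n_before = len(df)
            df = df.drop_duplicates(subset="transcript_id", keep="first")
            logger.warning(
                "dropped %d duplicate transcript-to-gene rows (identical assignments)",
                n_before - len(df),
            )
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def transcript_ids(self) -> list[str]:
        return self.table["transcript_id"].tolist()

    def gene_of(self) -> dict[str, str]:
        return dict(zip(self.table["transcript_id"], self.table["gene_id"]))

    def name_of(self) -> dict[str, str]:
        if "gene_name" not in self.table.columns:
            return {}
        sub = self.table.dropna(subset=["gene_name"])
        return dict(zip(sub["transcript_id"], sub["gene_name"]))

    def biotype_of(self) -> dict[str, str]:
        if "biotype" not in self.table.columns:
            return {}
        sub = self.table.dropna(subset=["biotype"])
        return dict(zip(sub["transcript_id"], sub["biotype"]))

    def gene_biotype_of(self) -> dict[str, str]:
        """First observed biotype per gene (for gene-level filtering)."""
        if "biotype" not in self.table.columns:
            return {}
        sub = self.table.dropna(subset=["biotype"])
        return sub.drop_duplicates(subset="gene_id").set_index("gene_id")["biotype"].to_dict()

    def normalized(self, ignore_version: bool = False, ignore_after_bar: bool = False) -> "TranscriptGeneMap":
        """Apply :func:`normalize_id` to the transcript ids (genes untouched)."""
        if not (ignore_version or ignore_after_bar):
            return self
        df = self.table.copy()
        df["transcript_id"] = [
            normalize_id(t, ignore_version, ignore_after_bar) for t in df["transcript_id"]
        ]
        return TranscriptGeneMap(df)


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    return {key: value for key, value in _ATTR_RE.findall(attr_field)}


def t2g_from_gtf(gtf_path: str | Path, keep_biotype: bool = False) -> TranscriptGeneMap:
    """Build a transcript-to-gene mapping from a GTF/GFF2 annotation.

    Records of feature type ``transcript`` contribute one mapping entry via
    their ``transcript_id`` / ``gene_id`` attributes; ``gene_name`` and (when
    ``keep_biotype``) the first of ``gene_biotype`` / ``transcript_biotype`` /
    ``gene_type`` are carried along.  Output order follows transcript-id
    sort order, so the mapping is independent of record order in the file.
    """
    gtf_path = Path(gtf_path)
    rows: list[dict[str, object]] = []
    with open(gtf_path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{gtf_path}: line {lineno}: expected 9 tab-separated fields")
            if fields[2] != "transcript":
                continue
            attrs = _parse_gtf_attributes(fields[8])
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise FormatError(
                    f"{gtf_path}: line {lineno}: transcript record lacks "
                    "transcript_id/gene_id attributes"
                )
            row: dict[str, object] = {
                "transcript_id": attrs["transcript_id"],
                "gene_id": attrs["gene_id"],
                "gene_name": attrs.get("gene_name"),
            }
            if keep_biotype:
                row["biotype"] = next(
                    (attrs[k] for k in BIOTYPE_ATTRIBUTE_ORDER if k in attrs), None
                )
            rows.append(row)
    if not rows:
        raise DataError(f"{gtf_path}: no transcript records found")
    df = pd.DataFrame(rows).sort_values("transcript_id", kind="stable").reset_index(drop=True)
    return TranscriptGeneMap(df)


def t2g_from_table(
    path: str | Path,
    transcript_column: str | int = 0,
    gene_column: str | int = 1,
    gene_name_column: str | int | None = None,
    biotype_column: str | int | None = None,
    sep: str | None = None,
) -> TranscriptGeneMap:
    """Build a mapping from a delimited table (TSV or CSV).

    Columns may be named (header required) or given by integer position.
    This is the ingestion path for locally saved BioMart exports.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    by_position = isinstance(transcript_column, int) and isinstance(gene_column, int)
    df = pd.read_csv(path, sep=sep, dtype=str, header=None if by_position else 0)
    df.columns = [str(c).strip() for c in df.columns] if not by_position else df.columns

    def pick(col: str | int, what: str) -> pd.Series:
        if isinstance(col, int):
            if col >= df.shape[1]:
                raise FormatError(f"{path}: no column at position {col} for {what}")
            return df.iloc[:, col]
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
        return df[col]

    out = pd.DataFrame(
        {
            "transcript_id": pick(transcript_column, "transcript ids"),
            "gene_id": pick(gene_column, "gene ids"),
        }
    )
    if gene_name_column is not None:
        out["gene_name"] = pick(gene_name_column, "gene names")
    elif not by_position and "gene_name" in df.columns:
        out["gene_name"] = df["gene_name"]
    if biotype_column is not None:
        out["biotype"] = pick(biotype_column, "biotypes")
    elif not by_position and "biotype" in df.columns:
        out["biotype"] = df["biotype"]
    elif not by_position and "gene_biotype" in df.columns:
        out["biotype"] = df["gene_biotype"]
    return TranscriptGeneMap(out)


def filter_by_biotype(
    dataset: "QuantDataset",
    mapping: TranscriptGeneMap,
    keep: Sequence[str],
    recompute_abundance: bool = False,
    drop_unmapped: bool = False,
) -> "QuantDataset":
    """Subset a dataset to features whose biotype is in ``keep``.

    Feature order is preserved.  With ``recompute_abundance`` each sample's
    retained TPM column is rescaled to sum to 1e6; counts and lengths are
    never rescaled.  Features absent from the mapping are a hard error
    unless ``drop_unmapped`` is set (then they are dropped with a logged
    count).
    """
    keep_set = set(keep)
    if not keep_set:
        raise DataError("filter_by_biotype: empty biotype list")
    lookup = (
        mapping.gene_biotype_of() if dataset.level == "gene" else mapping.biotype_of()
    )
    if not lookup:
        raise DataError("filter_by_biotype: mapping carries no biotype annotation")
    unmapped = [f for f in dataset.feature_ids if f not in lookup]
    if unmapped:
        if not drop_unmapped:
            shown = ", ".join(unmapped[:10])
            raise DataError(
                f"{len(unmapped)} feature(s) absent from the transcript-to-gene "
                f"mapping: {shown}" + (" ..." if len(unmapped) > 10 else "")
            )
        logger.warning("dropping %d features absent from the mapping", len(unmapped))
    mask = np.array(
        [f in lookup and lookup[f] in keep_set for f in dataset.feature_ids], dtype=bool
    )
    if not mask.any():
        raise DataError(
            "filter_by_biotype: no features match the requested biotypes "
            + repr(sorted(keep_set))
        )
    abundance = dataset.abundance[mask]
    if recompute_abundance:
        colsums = abundance.sum(axis=0)
        scale = np.divide(1e6, colsums, out=np.zeros_like(colsums), where=colsums > 0)
        abundance = abundance * scale
    replicates = None
    if dataset.replicates is not None:
        replicates = dataclasses.replace(
            dataset.replicates, tensor=dataset.replicates.tensor[mask], variance=None
        )
    return dataclasses.replace(
        dataset,
        feature_ids=[f for f, m in zip(dataset.feature_ids, mask) if m],
        counts=dataset.counts[mask],
        abundance=abundance,
        length=dataset.length[mask],
        feature_meta=dataset.feature_meta.loc[mask].reset_index(drop=True)
        if dataset.feature_meta is not None
        else None,
        replicates=replicates,
    )
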