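"""Serialization of datasets for downstream differential-expression tools.

The default target is an annotated-matrix HDF5 container (h5ad layout,
read and written through :mod:`anndata`) with samples as observations and
features as variables: counts in ``X``, abundance and length as layers,
optionally the replicate variance as a layer and the full replicate
tensor in ``uns``.  Alternatively a plain-text triplet of matrices
(counts / abundance / length, features as rows) plus a feature-annotation
table can be written as TSV or CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import infreps
from .errors import FormatError, UsageError
from .summarize import QuantDataset

logger = logging.getLogger(__name__)

EXPORT_FORMATS = ("annotated_hdf5", "tsv_triplet", "csv_triplet")
_TRIPLET_NAMES = ("counts", "abundance", "length")


@dataclass(frozen=True)
class ExportSpec:
    """What to write and how."""

    format: str = "annotated_hdf5"
    include_replicates: bool = False
    include_variance: bool = False
    counts_layer_name: str = "counts"

    def __post_init__(self) -> None:
        if self.format not in EXPORT_FORMATS:
            raise UsageError(
                f"unknown export format {self.format!r}; expected one of {EXPORT_FORMATS}"
            )
        if self.include_replicates and self.format != "annotated_hdf5":
            raise UsageError(
                "the replicate tensor can only be embedded in the annotated_hdf5 format"
            )


def _to_anndata(ds: QuantDataset, spec: ExportSpec, round_counts: bool):
    import anndata as ad

    counts = ds.counts.T
    if round_counts:
        counts = np.rint(counts)  # banker's rounding, half to even
    var = (
        ds.feature_meta.copy()
        if ds.feature_meta is not None
        else pd.DataFrame(index=pd.Index(ds.feature_ids, name="feature_id"))
    )
    var.index = pd.Index(ds.feature_ids, name="feature_id")
    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(index=pd.Index(ds.sample_ids, name="sample_id")),
        var=var,
        layers={"abundance": ds.abundance.T, "length": ds.length.T},
    )
    adata.uns["level"] = ds.level
    adata.uns["counts_layer_name"] = spec.counts_layer_name
    if ds.replicates is not None:
        adata.uns["replicate_kind"] = ds.replicates.kind
        if spec.include_variance:
            variance = ds.replicates.variance
            if variance is None:
                variance = infreps.replicate_variance(ds.replicates)
            adata.layers["variance"] = variance.T
        if spec.include_replicates:
            # feature x sample x replicate; stored unstructured as h5ad
            # layers cannot hold a 3-d array.
            adata.uns["inferential_replicates"] = ds.replicates.tensor
    elif spec.include_variance or spec.include_replicates:
        raise UsageError("replicate output requested but the dataset has no replicates")
    return adata


def write_dataset(
    ds: QuantDataset,
    spec: ExportSpec,
    out_path: str | Path,
    overwrite: bool = False,
    round_counts: bool = False,
) -> list[Path]:
    """Materialize a dataset; returns the written paths.

    ``annotated_hdf5`` writes a single h5ad file at ``out_path``.  The
    triplet formats treat ``out_path`` as a directory and write
    ``counts``/``abundance``/``length`` matrix files (features as rows,
    samples as columns) plus ``features`` annotations.  Counts are stored
    as reals; ``round_counts`` rounds them half-to-even for consumers
    demanding integers.
    """
    out_path = Path(out_path)
    if spec.format == "annotated_hdf5":
        if out_path.exists() and not overwrite:
            raise UsageError(f"{out_path} exists; pass overwrite to replace it")
        out_path.parent.mkdir(parents=True, exist_ok=True)
        _to_anndata(ds, spec, round_counts).write_h5ad(out_path)
        return [out_path]

    sep, suffix = ("\t", ".tsv") if spec.format == "tsv_triplet" else (",", ".csv")
    out_path.mkdir(parents=True, exist_ok=True)
    targets = {name: out_path / f"{name}{suffix}" for name in _TRIPLET_NAMES}
    targets["features"] = out_path / f"features{suffix}"
    existing = [p for p in targets.values() if p.exists()]
    if existing and not overwrite:
        raise UsageError(f"{existing[0]} exists; pass overwrite to replace it")
    index = pd.Index(ds.feature_ids, name="feature_id")
    for name in _TRIPLET_NAMES:
        matrix = getattr(ds, name)
        if name == "counts" and round_counts:
            matrix = np.rint(matrix)
        frame = pd.DataFrame(matrix, index=index, columns=ds.sample_ids)
        frame.to_csv(targets[name], sep=sep, float_format="%.12g", lineterminator="\n")
    meta = ds.feature_meta if ds.feature_meta is not None else pd.DataFrame(index=index)
    meta = meta.copy()
    meta.index = index
    meta.to_csv(targets["features"], sep=sep, lineterminator="\n")
    if spec.include_variance:
        if ds.replicates is None:
            raise UsageError("replicate output requested but the dataset has no replicates")
        variance = ds.replicates.variance
        if variance is None:
            variance = infreps.replicate_variance(ds.replicates)
        var_path = out_path / f"variance{suffix}"
        pd.DataFrame(variance, index=index, columns=ds.sample_ids).to_csv(
            var_path, sep=sep, float_format="%.12g", lineterminator="\n"
        )
        targets["variance"] = var_path
    return list(targets.values())


def read_dataset(path: str | Path) -> QuantDataset:
    """Read back an ``annotated_hdf5`` container written by :func:`write_dataset`.

    Lossless inverse up to floating-point storage; sample and feature
    orders are preserved.
    """
    import anndata as ad

    path = Path(path)
    try:
        adata = ad.read_h5ad(path)
    except Exception as exc:
        raise FormatError(f"{path}: not a readable annotated-HDF5 container: {exc}") from exc
    for layer in ("abundance", "length"):
        if layer not in adata.layers:
            raise FormatError(f"{path}: missing layer {layer!r}")
    replicates = None
    if "inferential_replicates" in adata.uns:
        replicates = infreps.InferentialReplicates(
            tensor=np.asarray(adata.uns["inferential_replicates"]),
            kind=str(adata.uns.get("replicate_kind", "unknown")),
            variance=np.asarray(adata.layers["variance"]).T
            if "variance" in adata.layers
            else None,
        )
    meta = adata.var.reset_index(drop=True) if adata.var.shape[1] else None
    return QuantDataset(
        feature_ids=[str(v) for v in adata.var_names],
        sample_ids=[str(o) for o in adata.obs_names],
        counts=np.asarray(adata.X).T,
        abundance=np.asarray(adata.layers["abundance"]).T,
        length=np.asarray(adata.layers["length"]).T,
        level=str(adata.uns.get("level", "gene")),
        replicates=replicates,
        feature_meta=meta,
    )
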