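"""Cell-level quality control, normalization, and composition summaries."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Cell QC cutoffs.

    A cell is removed when it has strictly fewer than ``min_genes_detected``
    genes detected or a strictly greater fraction than ``max_mito_fraction``
    of its counts on mitochondrial genes (identified by ``mito_prefix``);
    ties are retained.
    """

    min_genes_detected: int = 500
    max_mito_fraction: float = 0.15
    mito_prefix: str = "mt-"

    def validate(self) -> None:
        if self.min_genes_detected < 0:
            raise ValueError("min_genes_detected must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def filter_cells(adata: ad.AnnData, qc: QCThresholds | None = None) -> ad.AnnData:
    """Remove low-quality cells; gene set is unchanged.

    Retains exactly the cells with ``genes_detected >= min_genes_detected``
    and ``mito_fraction <= max_mito_fraction``.  The per-criterion removal
    counts are logged.  An all-cells-removed result is a warning, not an
    error.
    """
    qc = qc or QCThresholds()
    qc.validate()
    X = _dense(adata.X)
    genes_detected = (X > 0).sum(axis=1)
    totals = X.sum(axis=1)
    mito = np.asarray(
        [g.startswith(qc.mito_prefix) for g in adata.var_names], dtype=bool
    )
    mito_counts = X[:, mito].sum(axis=1) if mito.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    low_genes = genes_detected < qc.min_genes_detected
    high_mito = mito_frac > qc.max_mito_fraction
    keep = ~(low_genes | high_mito)
    log.info(
        "QC: removed %d/%d cells (%d low gene count, %d high mito fraction)",
        int((~keep).sum()), adata.n_obs, int(low_genes.sum()), int(high_mito.sum()),
    )
    if not keep.any():
        warnings.warn("QC removed every cell; returning an empty matrix", stacklevel=2)
    return adata[keep].copy()


def normalize(adata: ad.AnnData) -> ad.AnnData:
    """Per-cell normalization to counts-per-10k followed by log2(x + 1).

    value(g, c) = log2(count(g, c) / total(c) * 10000 + 1).  Zero counts map
    to exactly 0; cells whose total count is zero map to all zeros.
    """
    X = _dense(adata.X).astype(np.float64)
    totals = X.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(totals > 0, X / np.where(totals > 0, totals, 1.0) * 1e4, 0.0)
    out = adata.copy()
    out.X = np.log2(scaled + 1.0)
    out.uns["normalization"] = "log2_cp10k"
    return out


def composition(
    ann: pd.DataFrame, subset: set[str] | None = None
) -> pd.DataFrame:
    """Cell-type proportions per sample (and per group).

    ``ann`` needs columns ``cell_type``, ``sample_id``, ``group_id``.  With
    ``subset`` given, fractions are of the subset total per sample (e.g.
    fractions of total epithelial cells); a sample with no subset member
    cells gets NaN fractions.
    """
    required = {"cell_type", "sample_id", "group_id"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    types = sorted(set(subset)) if subset is not None else sorted(ann["cell_type"].unique())
    sub = ann[ann["cell_type"].isin(types)]
    counts = (
        sub.groupby(["group_id", "sample_id"], observed=True)["cell_type"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=types, fill_value=0)
    )
    # keep samples that lost every cell to the subset as NaN rows
    all_samples = ann[["group_id", "sample_id"]].drop_duplicates()
    counts = counts.reindex(
        pd.MultiIndex.from_frame(all_samples, names=["group_id", "sample_id"])
    )
    totals = counts.sum(axis=1)
    frac = counts.div(totals.where(totals > 0), axis=0)
    frac.columns.name = "cell_type"
    return frac
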