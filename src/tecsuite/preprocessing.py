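"""QC filter cascades and the library-size normalization contract.

The cell/gene filter cascade runs in a fixed order: (1) a preliminary
filter removing cells with fewer than ``prelim_genes_min`` detected genes
and genes detected in fewer than ``gene_min_cells`` cells, (2) doublet
exclusion on a precomputed per-cell doublet score, (3) per-cell QC metric
exclusion (mitochondrial percentage, total UMIs, detected genes).  All
"over"/"less than" comparisons are strict; "at least" is inclusive.  A
QC report attributes every removed cell to the first stage that removed it.

Normalization scales each cell to a fixed total (default 10,000) on the
linear scale, optionally followed by a natural log1p transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "filter_protein_coding",
    "qc_filter",
    "normalize",
    "atlas_detection_filter",
    "clip_for_display",
]


@dataclass
class QCThresholds:
    """Cutoffs of the cell/gene QC cascade (defaults as used throughout)."""

    doublet_score_max: float = 0.2   # cells with score > this are removed
    mito_pct_max: float = 5.0        # percent of counts in mito genes, strict >
    umi_min: float = 1_000.0         # strict <
    umi_max: float = 70_000.0        # strict >
    genes_min: float = 1_000.0       # strict <
    genes_max: float = 8_500.0       # strict >
    prelim_genes_min: int = 100      # cells with fewer detected genes removed
    gene_min_cells: int = 20         # genes detected in fewer cells removed

    def __post_init__(self) -> None:
        if not self.umi_min < self.umi_max:
            raise ValueError("umi_min must be < umi_max")
        if not self.genes_min < self.genes_max:
            raise ValueError("genes_min must be < genes_max")


def _detected(X) -> tuple[np.ndarray, np.ndarray]:
    """(genes detected per cell, cells detecting each gene)."""
    B = X > 0
    if sp.issparse(B):
        return np.asarray(B.sum(axis=1)).ravel(), np.asarray(B.sum(axis=0)).ravel()
    return B.sum(axis=1), B.sum(axis=0)


def filter_protein_coding(adata: ad.AnnData, biotype_col: str = "biotype",
                          value: str = "protein_coding",
                          case_insensitive: bool = False) -> ad.AnnData:
    """Retain only genes whose biotype annotation matches ``value``.

    Matching is exact by default; set ``case_insensitive`` to fold case.
    The cell set is unchanged.  Retaining zero genes is allowed (warning).
    """
    if biotype_col not in adata.var:
        raise ValueError(f"var column {biotype_col!r} (gene biotypes) is missing")
    biotypes = adata.var[biotype_col].astype(str)
    if case_insensitive:
        keep = biotypes.str.lower() == value.lower()
    else:
        keep = biotypes == value
    if not keep.any():
        logger.warning("protein-coding filter retained zero genes")
    return adata[:, keep.to_numpy()].copy()


def qc_filter(adata: ad.AnnData, thresholds: QCThresholds | None = None,
              doublet_col: str = "doublet_score",
              mito_prefix: str = "mt-",
              mito_genes: list[str] | None = None,
              ) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply the QC cascade; returns the filtered AnnData and a stage report.

    The mitochondrial gene set is either an explicit list (``mito_genes``)
    or all genes whose name starts with ``mito_prefix``; it may be empty.
    The doublet-score column must exist (zero-fill it to disable the stage).
    """
    t = thresholds or QCThresholds()
    if doublet_col not in adata.obs:
        raise ValueError(
            f"obs column {doublet_col!r} is missing: supply precomputed doublet "
            "scores or zero-fill the column to disable doublet exclusion"
        )
    report_rows = []
    cur = adata

    def _record(stage: str, cells_removed: int, genes_removed: int) -> None:
        report_rows.append({
            "stage": stage, "cells_removed": int(cells_removed),
            "genes_removed": int(genes_removed),
            "cells_remaining": cur.n_obs, "genes_remaining": cur.n_vars,
        })

    # stage 1: preliminary cell filter, then gene filter
    genes_per_cell, _ = _detected(cur.X)
    keep_cells = genes_per_cell >= t.prelim_genes_min
    removed = int((~keep_cells).sum())
    cur = cur[keep_cells].copy()
    _record("prelim_min_genes", removed, 0)

    _, cells_per_gene = _detected(cur.X)
    keep_genes = cells_per_gene >= t.gene_min_cells
    removed_g = int((~keep_genes).sum())
    cur = cur[:, keep_genes].copy()
    _record("prelim_gene_min_cells", 0, removed_g)

    # stage 2: doublets
    keep_cells = cur.obs[doublet_col].to_numpy() <= t.doublet_score_max
    removed = int((~keep_cells).sum())
    cur = cur[keep_cells].copy()
    _record("doublet_score", removed, 0)

    # stage 3: per-cell QC metrics, attributed mito -> UMI -> genes
    X = cur.X
    totals = np.asarray(X.sum(axis=1)).ravel() if sp.issparse(X) else X.sum(axis=1)
    genes_per_cell, _ = _detected(X)
    if mito_genes is not None:
        mito_mask = cur.var_names.isin(mito_genes)
    else:
        mito_mask = cur.var_names.str.startswith(mito_prefix)
    if mito_mask.any():
        mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    else:
        mito_counts = np.zeros(cur.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(totals > 0, 100.0 * mito_counts / totals, 0.0)

    fail_mito = mito_pct > t.mito_pct_max
    fail_umi = (totals > t.umi_max) | (totals < t.umi_min)
    fail_genes = (genes_per_cell > t.genes_max) | (genes_per_cell < t.genes_min)

    keep = ~fail_mito
    cur2 = cur[keep].copy()
    n_mito = int(fail_mito.sum())
    fail_umi, fail_genes = fail_umi[keep], fail_genes[keep]
    cur = cur2
    _record("mito_pct", n_mito, 0)

    keep = ~fail_umi
    n_umi = int(fail_umi.sum())
    fail_genes = fail_genes[keep]
    cur = cur[keep].copy()
    _record("umi_range", n_umi, 0)

    n_g = int(fail_genes.sum())
    cur = cur[~fail_genes].copy()
    _record("gene_range", n_g, 0)

    report = pd.DataFrame(report_rows)
    return cur, report


def normalize(adata: ad.AnnData, target_sum: float = 10_000.0,
              log1p: bool = False) -> ad.AnnData:
    """Scale every cell to ``target_sum`` total counts (linear scale).

    All-zero cells are left as zeros (with a warning).  When ``log1p`` is
    set, a natural log(1 + x) transform follows; the flag is recorded in
    ``uns['normalization']``.
    """
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel() if sp.issparse(X) else np.asarray(X.sum(axis=1), dtype=float).ravel()
    zero = totals <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cells left unnormalized")
    scale = np.where(zero, 0.0, target_sum / np.where(zero, 1.0, totals))
    if sp.issparse(X):
        Xn = sp.diags(scale) @ X.astype(float).tocsr()
        if log1p:
            Xn.data = np.log1p(Xn.data)
    else:
        Xn = np.asarray(X, dtype=float) * scale[:, None]
        if log1p:
            Xn = np.log1p(Xn)
    out = adata.copy()
    out.X = Xn
    out.uns["normalization"] = {"target_sum": float(target_sum), "log1p": bool(log1p)}
    return out


def atlas_detection_filter(adata: ad.AnnData, min_genes_per_cell: int = 500,
                           min_count: int = 2, min_cells: int = 100) -> ad.AnnData:
    """Atlas-side detection filter for specificity scoring.

    Cells with fewer than ``min_genes_per_cell`` detected genes are removed
    first; then genes without at least ``min_count`` raw counts in at least
    ``min_cells`` cells (both bounds inclusive) are removed.
    """
    genes_per_cell, _ = _detected(adata.X)
    cur = adata[genes_per_cell >= min_genes_per_cell].copy()
    B = cur.X >= min_count
    n_cells_high = (np.asarray(B.sum(axis=0)).ravel() if sp.issparse(B)
                    else B.sum(axis=0))
    return cur[:, n_cells_high >= min_cells].copy()


def clip_for_display(values, lower_pct: float = 1.0, upper_pct: float = 99.0):
    """Clip a per-cell value vector to its [lower, upper] percentiles
    (linear-interpolation percentiles), for colormap display."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("clip_for_display requires a nonempty vector")
    lo, hi = np.percentile(v, [lower_pct, upper_pct])
    return np.clip(v, lo, hi)
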