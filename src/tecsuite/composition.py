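"""Per-sample cell-type composition and per-cell transcriptomic diversity.

Composition: the fraction of each sample's cells carrying each cell-type
label, and per cell type the mean over test-genotype samples of
log2((fraction + delta) / (mean reference fraction + delta)), flagged when
the magnitude exceeds a threshold (default 0.5).

Diversity: per cell, the number of genes with linear normalized expression
strictly above a threshold (default 0.1), the fraction of those expressed
genes classified as TRAs, and per-gene mean log-transformed expression by
genotype for diagonal scatter comparisons.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "composition_fractions",
    "composition_log2fc",
    "genes_per_cell",
    "tra_fraction_per_cell",
    "mean_log_expression",
]


def composition_fractions(cells: pd.DataFrame, sample_col: str = "sample_id",
                          celltype_col: str = "cell_type") -> pd.DataFrame:
    """Sample x cell-type matrix of proportions (each row sums to 1)."""
    for col in (sample_col, celltype_col):
        if col not in cells:
            raise ValueError(f"cell table misses column {col!r}")
    counts = pd.crosstab(cells[sample_col], cells[celltype_col])
    counts = counts.loc[counts.sum(axis=1) > 0]
    if counts.empty:
        raise ValueError("no non-empty samples in the cell table")
    return counts.div(counts.sum(axis=1), axis=0)


def composition_log2fc(fractions: pd.DataFrame, genotype_of_sample: pd.Series,
                       reference_genotype: str = "WT",
                       test_genotype: str | None = None,
                       flag_threshold: float = 0.5, delta: float = 1e-6,
                       per_pair: bool = False) -> pd.DataFrame:
    """Per cell type, mean log2 fold change of test-sample fractions over
    the reference, with a flag for |mean_log2fc| > ``flag_threshold``.

    By default the reference fraction is the arithmetic mean across
    reference samples; ``per_pair`` instead averages log2 ratios over all
    (test sample, reference sample) pairs.  ``delta`` guards empty types.
    """
    genotype_of_sample = pd.Series(genotype_of_sample).astype(str)
    ref_samples = genotype_of_sample.index[genotype_of_sample == reference_genotype]
    ref_samples = [s for s in ref_samples if s in fractions.index]
    if not ref_samples:
        raise ValueError(f"reference genotype {reference_genotype!r} has no samples")
    if test_genotype is None:
        others = sorted(set(genotype_of_sample) - {reference_genotype})
        if len(others) != 1:
            raise ValueError(f"test genotype ambiguous among {others}")
        test_genotype = others[0]
    test_samples = [s for s in genotype_of_sample.index
                    if genotype_of_sample[s] == test_genotype and s in fractions.index]
    if not test_samples:
        raise ValueError(f"test genotype {test_genotype!r} has no samples")

    f_test = fractions.loc[test_samples]
    if per_pair:
        ratios = [
            np.log2((f_test.loc[ts] + delta) / (fractions.loc[rs] + delta))
            for ts in test_samples for rs in ref_samples
        ]
        mean_lfc = pd.concat(ratios, axis=1).mean(axis=1)
    else:
        f_ref = fractions.loc[ref_samples].mean(axis=0)
        mean_lfc = np.log2((f_test + delta).div(f_ref + delta, axis=1)).mean(axis=0)
    return pd.DataFrame({
        "mean_log2fc": mean_lfc,
        "flagged": mean_lfc.abs() > flag_threshold,
    })


def _linear_matrix(norm) -> tuple[np.ndarray | sp.spmatrix, pd.Index | None]:
    if isinstance(norm, ad.AnnData):
        if norm.uns.get("normalization", {}).get("log1p"):
            raise ValueError("linear (not log-transformed) normalized values required")
        return norm.X, norm.var_names
    return norm, None


def genes_per_cell(norm, expr_threshold: float = 0.1) -> np.ndarray:
    """Per-cell count of genes with normalized expression strictly above
    ``expr_threshold``."""
    X, _ = _linear_matrix(norm)
    B = X > expr_threshold
    return np.asarray(B.sum(axis=1)).ravel() if sp.issparse(B) else B.sum(axis=1)


def tra_fraction_per_cell(norm, tra_genes, expr_threshold: float = 0.1) -> np.ndarray:
    """Per-cell fraction of expressed genes (normalized expression >
    threshold) that are classified TRAs.

    ``tra_genes`` is a boolean Series indexed by gene (or a boolean array
    aligned to the matrix columns); genes absent from it count as non-TRA
    (with a warning).  Cells expressing no gene report 0.
    """
    X, gene_names = _linear_matrix(norm)
    n_genes = X.shape[1]
    if isinstance(tra_genes, pd.Series) and gene_names is not None:
        missing = gene_names.difference(tra_genes.index)
        if len(missing):
            warnings.warn(f"{len(missing)} genes lack a TRA call; treated as non-TRA")
        is_tra = tra_genes.reindex(gene_names, fill_value=False).to_numpy(dtype=bool)
    else:
        is_tra = np.asarray(tra_genes, dtype=bool)
        if is_tra.shape != (n_genes,):
            raise ValueError("tra_genes must align with the gene axis")
    B = X > expr_threshold
    if sp.issparse(B):
        n_expr = np.asarray(B.sum(axis=1)).ravel()
        n_tra = np.asarray(B[:, is_tra].sum(axis=1)).ravel()
    else:
        n_expr = B.sum(axis=1)
        n_tra = B[:, is_tra].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_expr > 0, n_tra / np.where(n_expr > 0, n_expr, 1), 0.0)


def mean_log_expression(norm, genotypes, subset_mask=None) -> pd.DataFrame:
    """Per-gene mean of ln(1 + normalized expression) per genotype, over an
    optional cell subset; one column per genotype (for diagonal scatters)."""
    X, gene_names = _linear_matrix(norm)
    genotypes = np.asarray(genotypes)
    if subset_mask is not None:
        subset_mask = np.asarray(subset_mask, dtype=bool)
        X = X[subset_mask]
        genotypes = genotypes[subset_mask]
    if X.shape[0] == 0:
        raise ValueError("the cell subset contains no cells")
    cols = {}
    for g in np.unique(genotypes):
        sub = X[genotypes == g]
        if sub.shape[0] == 0:
            raise ValueError(f"genotype {g!r} has no cells in the subset")
        if sp.issparse(sub):
            sub = sub.copy()
            sub.data = np.log1p(sub.data)
            cols[g] = np.asarray(sub.mean(axis=0)).ravel()
        else:
            cols[g] = np.log1p(np.asarray(sub, dtype=float)).mean(axis=0)
    return pd.DataFrame(cols, index=gene_names)
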