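"""Independent brute-force enumerations used to cross-check the filter
cascades.  Pure-python loops, deliberately separate from the package code."""

import numpy as np


def brute_force_qc(counts, doublet, mito_mask, t):
    """Enumerate the QC cascade on a dense matrix; returns kept (cells, genes)."""
    counts = np.asarray(counts, dtype=float)
    cells = list(range(counts.shape[0]))
    genes = list(range(counts.shape[1]))
    cells = [i for i in cells if (counts[i] > 0).sum() >= t.prelim_genes_min]
    genes = [j for j in genes
             if sum(counts[i, j] > 0 for i in cells) >= t.gene_min_cells]
    cells = [i for i in cells if doublet[i] <= t.doublet_score_max]
    kept = []
    for i in cells:
        row = counts[i, genes]
        total = row.sum()
        mito = counts[np.ix_([i], [j for j in genes if mito_mask[j]])].sum()
        pct = 100 * mito / total if total > 0 else 0.0
        n_det = (row > 0).sum()
        if pct > t.mito_pct_max:
            continue
        if total > t.umi_max or total < t.umi_min:
            continue
        if n_det > t.genes_max or n_det < t.genes_min:
            continue
        kept.append(i)
    return kept, genes


def brute_force_atlas_filter(counts, min_genes, min_count, min_cells):
    counts = np.asarray(counts)
    cells = [i for i in range(counts.shape[0])
             if (counts[i] > 0).sum() >= min_genes]
    genes = [j for j in range(counts.shape[1])
             if sum(counts[i, j] >= min_count for i in cells) >= min_cells]
    return cells, genes


def brute_force_de_filter(stats, t):
    """Row-by-row re-evaluation of the DE threshold rules."""
    out = []
    for _, row in stats.iterrows():
        frac = (max(row["frac_nonzero_a"], row["frac_nonzero_b"])
                if t.frac_mode == "max" else row["frac_nonzero_a"])
        if not row["bayes_factor"] > t.bf_min:
            continue
        if not abs(row["lfc_mean"]) > t.lfc_abs_min:
            continue
        if not frac >= t.frac_min:
            continue
        if t.peak_min is not None and not row["peak_expr"] > t.peak_min:
            continue
        out.append(row["gene"])
    return out


def brute_force_eligibility(cells, min_cells=30):
    types = sorted(cells["cell_type"].unique())
    samples = sorted(cells["sample_id"].unique())
    return [ct for ct in types
            if all(((cells["cell_type"] == ct)
                    & (cells["sample_id"] == s)).sum() >= min_cells
                   for s in samples)]
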