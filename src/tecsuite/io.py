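"""Plain-text I/O: Matrix Market triplet directories and TSV tables.

A counts directory holds ``matrix.mtx`` (cells x genes, integer),
``genes.tsv`` (gene_id, biotype, plus any extra var columns),
``barcodes.tsv`` (cell ids) and ``cells.tsv`` (per-cell metadata).
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["write_counts_dir", "read_counts_dir", "write_tsv", "read_tsv"]


def write_counts_dir(adata: ad.AnnData, path) -> Path:
    """Write an AnnData as a Matrix Market + TSV triplet directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(path / "matrix.mtx"), X.tocoo())
    var = adata.var.copy()
    var.insert(0, "gene_id", adata.var_names)
    var.to_csv(path / "genes.tsv", sep="\t", index=False)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        path / "barcodes.tsv", sep="\t", index=False, header=False
    )
    obs = adata.obs.copy()
    obs.insert(0, "cell_id", adata.obs_names)
    obs.to_csv(path / "cells.tsv", sep="\t", index=False)
    return path


def read_counts_dir(path) -> ad.AnnData:
    """Read a counts directory written by :func:`write_counts_dir`."""
    path = Path(path)
    X = sp.csr_matrix(scipy.io.mmread(str(path / "matrix.mtx")))
    genes = pd.read_csv(path / "genes.tsv", sep="\t").set_index("gene_id")
    genes.index = genes.index.astype(str)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.DataFrame(index=barcodes.to_numpy())
    cells_path = path / "cells.tsv"
    if cells_path.exists():
        obs = pd.read_csv(cells_path, sep="\t").set_index("cell_id")
        obs.index = obs.index.astype(str)
    if X.dtype.kind == "f" and np.allclose(X.data % 1, 0):
        X = X.astype(np.int64)
    return ad.AnnData(X=X, obs=obs, var=genes)


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
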