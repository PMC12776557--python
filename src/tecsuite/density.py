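"""Differential abundance as a conditional-KDE log ratio on a 2D embedding.

For each genotype g, a product-Gaussian kernel density estimate is fitted
to that genotype's embedding coordinates with the multivariate
normal-reference bandwidth per dimension,

    h_d = sigma_d * (4 / ((d + 2) * m)) ** (1 / (d + 4)),   d = 2,

where m is the number of cells of genotype g and sigma_d the sample
standard deviation.  Each genotype's density integrates to 1, so the
per-cell statistic

    log_ratio(x) = ln f_test(x) - ln f_reference(x)

reflects *relative* composition: positive where the test genotype (e.g. a
KO) is denser, negative where the reference (WT) is denser, near zero
where both are equally dense.  Densities are evaluated in log space
(logsumexp over kernels), so the ratio is finite everywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

__all__ = [
    "normal_reference_bandwidth",
    "gaussian_kde_logpdf",
    "conditional_kde",
    "log_density_ratio",
    "ConditionalDensityRatio",
    "plot_density_ratio",
]

_LOG_2PI = np.log(2.0 * np.pi)


def normal_reference_bandwidth(coords: np.ndarray) -> np.ndarray:
    """Per-dimension normal-reference bandwidth for a (m, d) point set."""
    coords = np.asarray(coords, dtype=float)
    m, d = coords.shape
    if m < 2:
        raise ValueError("normal-reference bandwidth needs at least 2 points; "
                         "pass an explicit bandwidth for smaller samples")
    sigma = coords.std(axis=0, ddof=1)
    if (sigma <= 0).any():
        raise ValueError(
            "zero variance in an embedding dimension; jitter the coordinates "
            "or pass an explicit bandwidth"
        )
    return sigma * (4.0 / ((d + 2) * m)) ** (1.0 / (d + 4))


def gaussian_kde_logpdf(train: np.ndarray, bandwidth: np.ndarray,
                        query: np.ndarray, chunk: int = 1024) -> np.ndarray:
    """Log density of a product-Gaussian KDE at the query points."""
    train = np.atleast_2d(np.asarray(train, dtype=float))
    query = np.atleast_2d(np.asarray(query, dtype=float))
    h = np.asarray(bandwidth, dtype=float)
    if (h <= 0).any():
        raise ValueError("bandwidths must be positive")
    m, d = train.shape
    const = -np.log(m) - np.sum(np.log(h)) - 0.5 * d * _LOG_2PI
    out = np.empty(query.shape[0])
    for start in range(0, query.shape[0], chunk):
        q = query[start:start + chunk]
        # (q, m) matrix of summed squared standardized distances
        z = ((q[:, None, :] - train[None, :, :]) / h) ** 2
        out[start:start + chunk] = logsumexp(-0.5 * z.sum(axis=2), axis=1) + const
    return out


def conditional_kde(coords: np.ndarray, genotypes, genotype: str,
                    bandwidth=None):
    """KDE of one genotype's cells: returns ``(logpdf callable, bandwidths)``.

    ``bandwidth=None`` applies the normal-reference rule; an explicit pair
    of per-dimension bandwidths may be given instead (required for fewer
    than 2 cells).
    """
    coords = np.asarray(coords, dtype=float)
    genotypes = np.asarray(genotypes)
    mask = genotypes == genotype
    if not mask.any():
        raise ValueError(f"unknown genotype label {genotype!r}")
    pts = coords[mask]
    h = (normal_reference_bandwidth(pts) if bandwidth is None
         else np.asarray(bandwidth, dtype=float))
    return (lambda q: gaussian_kde_logpdf(pts, h, q)), h


class ConditionalDensityRatio(BaseEstimator):
    """Per-cell log ratio of genotype-conditional kernel densities.

    Parameters
    ----------
    reference : str, default "WT"
        Genotype in the denominator (negative log ratio = denser here).
    test : str or None
        Genotype in the numerator; ``None`` picks the single non-reference
        label (an error if several are present).
    bandwidth : "normal_reference" or pair of floats
        Per-dimension kernel bandwidths; the default applies the
        normal-reference rule per genotype.
    min_cells : int, default 50
        Minimum cells required per genotype.

    Attributes
    ----------
    bandwidths_ : dict genotype -> per-dimension bandwidth array.
    log_ratio_ : log ratio at every fitted cell (natural log).
    """

    def __init__(self, reference: str = "WT", test: str | None = None,
                 bandwidth="normal_reference", min_cells: int = 50):
        self.reference = reference
        self.test = test
        self.bandwidth = bandwidth
        self.min_cells = min_cells

    def fit(self, X, y):
        """Fit per-genotype KDEs: ``X`` is (cells, 2) embedding coordinates,
        ``y`` the per-cell genotype labels."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("exactly 2 embedding dimensions are required")
        labels = set(np.unique(y))
        if self.reference not in labels:
            raise ValueError(f"reference genotype {self.reference!r} not present")
        if self.test is None:
            others = sorted(labels - {self.reference})
            if len(others) != 1:
                raise ValueError(
                    f"test genotype is ambiguous among {others}; set `test`"
                )
            test = others[0]
        else:
            if self.test not in labels:
                raise ValueError(f"unknown genotype label {self.test!r}")
            test = self.test
        self.test_ = test
        self._train, self.bandwidths_ = {}, {}
        for g in (self.reference, test):
            pts = X[y == g]
            if pts.shape[0] < self.min_cells:
                raise ValueError(
                    f"genotype {g!r} has {pts.shape[0]} cells; "
                    f"at least {self.min_cells} required"
                )
            if isinstance(self.bandwidth, str):
                if self.bandwidth != "normal_reference":
                    raise ValueError(f"unknown bandwidth rule {self.bandwidth!r}")
                h = normal_reference_bandwidth(pts)
            else:
                h = np.asarray(self.bandwidth, dtype=float)
            self._train[g] = pts
            self.bandwidths_[g] = h
        self.log_ratio_ = self.score_samples(X)
        return self

    def score_samples(self, X) -> np.ndarray:
        """Natural-log density ratio (test over reference) at points X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        log_test = gaussian_kde_logpdf(self._train[self.test_],
                                       self.bandwidths_[self.test_], X)
        log_ref = gaussian_kde_logpdf(self._train[self.reference],
                                      self.bandwidths_[self.reference], X)
        return log_test - log_ref

    def fit_predict(self, X, y) -> np.ndarray:
        return self.fit(X, y).log_ratio_


def log_density_ratio(coords, genotypes, reference: str = "WT",
                      test: str | None = None, bandwidth="normal_reference",
                      min_cells: int = 50, cell_ids=None) -> pd.Series:
    """Per-cell log density ratio (test over reference) as a Series."""
    est = ConditionalDensityRatio(reference=reference, test=test,
                                  bandwidth=bandwidth, min_cells=min_cells)
    ratio = est.fit_predict(np.asarray(coords, dtype=float), genotypes)
    return pd.Series(ratio, index=cell_ids, name="log_ratio")


def plot_density_ratio(coords, log_ratio, ax=None, point_size: float = 3.0):
    """Diagnostic scatter: cells colored by log ratio on a symmetric
    diverging scale (red = test-enriched, blue = reference-enriched)."""
    import matplotlib.pyplot as plt

    coords = np.asarray(coords, dtype=float)
    log_ratio = np.asarray(log_ratio, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    lim = np.abs(log_ratio).max() or 1.0
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=log_ratio, s=point_size,
                    cmap="RdBu_r", vmin=-lim, vmax=lim, linewidths=0)
    ax.figure.colorbar(sc, ax=ax, label="log density ratio")
    ax.set_xlabel("umap1")
    ax.set_ylabel("umap2")
    return ax
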