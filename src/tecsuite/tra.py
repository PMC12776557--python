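"""Tissue-restriction scoring and TRA classification.

A gene's mean normalized expression across ``n`` groups (tissues or cell
types) is squared and renormalized to a probability vector

    p_i = m_i**2 / sum_j m_j**2 .

Two specificity statistics are computed on ``p``:

* Shannon entropy ``H = -sum p_i log2 p_i`` (bits), mapped to the entropy
  score ``1 - H / log2(n)`` in [0, 1];
* the Tau index ``tau = sum_i (1 - p_i / max_j p_j) / (n - 1)``.

Both are 0 for a uniform profile and 1 for a single-group profile.  A
logarithmic model ``entropy_score = a + b * ln(tau)`` fitted over all
scoreable genes translates a chosen Tau threshold into an entropy-score
threshold, and a gene is a TRA if it passes *either* threshold
(inclusive comparisons).

:class:`TRAClassifier` wraps the whole procedure as an sklearn-style
estimator: ``fit(X, y)`` takes normalized expression (cells x genes) and
per-cell group labels, builds the group profile, scores every gene and
calibrates the thresholds; ``predict()`` returns the per-gene TRA calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

__all__ = [
    "ThresholdPair",
    "group_mean_profile",
    "squared_probability",
    "entropy_score",
    "tau",
    "score_specificity",
    "calibrate_entropy_threshold",
    "classify_tra",
    "TRAClassifier",
]


@dataclass
class ThresholdPair:
    """A Tau threshold and its calibrated entropy-score counterpart."""

    tau_star: float
    entropy_star: float
    fit_params: tuple[float, float]  # (a, b) of entropy_score = a + b ln(tau)


def group_mean_profile(norm, labels, gene_names=None) -> pd.DataFrame:
    """Mean expression per gene per group (genes x groups DataFrame).

    ``norm`` may be an AnnData (X used; var_names as genes) or a cells x
    genes array/sparse matrix.  Empty groups cannot arise from per-cell
    labels; groups are the distinct label values, in sorted order.
    """
    if isinstance(norm, ad.AnnData):
        X, gene_names = norm.X, norm.var_names.to_numpy()
    else:
        X = norm
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("one label per cell is required")
    groups, inv = np.unique(labels, return_inverse=True)
    G = sp.csr_matrix(
        (np.ones(len(inv)), (inv, np.arange(len(inv)))),
        shape=(len(groups), len(inv)),
    )
    sums = G @ X
    sums = sums.toarray() if sp.issparse(sums) else np.asarray(sums)
    counts = np.bincount(inv, minlength=len(groups)).astype(float)
    means = (sums / counts[:, None]).T  # genes x groups
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(means.shape[0])]
    return pd.DataFrame(means, index=gene_names, columns=groups)


def squared_probability(profile: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Square each gene's group means and renormalize rows to sum to 1.

    All-zero rows come back as NaN rows: such genes are unscoreable and
    are excluded from calibration and classification downstream.
    """
    m = np.asarray(profile, dtype=float)
    one_dim = m.ndim == 1
    m = np.atleast_2d(m)
    if (m < 0).any():
        raise ValueError("group means must be nonnegative")
    sq = m ** 2
    denom = sq.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(denom > 0, sq / np.where(denom > 0, denom, 1.0), np.nan)
    return p[0] if one_dim else p


def entropy_score(p: np.ndarray, n: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Shannon entropy in bits and the [0, 1] entropy score ``1 - H/log2 n``.

    ``0 * log2(0)`` is taken as 0.  Requires n >= 2 groups.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    n = p.shape[1] if n is None else n
    if n < 2:
        raise ValueError("entropy score requires at least 2 groups")
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    H = -terms.sum(axis=1)
    score = 1.0 - H / np.log2(n)
    H = np.where(np.isnan(p).any(axis=1), np.nan, H)
    score = np.where(np.isnan(H), np.nan, score)
    return H.squeeze(), score.squeeze()


def tau(p: np.ndarray) -> np.ndarray:
    """Tau specificity index of one probability vector (or a stack of them):
    ``sum_i (1 - p_i/max_j p_j) / (n - 1)``; 0 = uniform, 1 = single group."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    mx = p.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = np.where(mx > 0, p / np.where(mx > 0, mx, 1.0), np.nan)
    t = (1.0 - xhat).sum(axis=1) / (p.shape[1] - 1)
    return t.squeeze()


def score_specificity(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-gene specificity table from a genes x groups mean-expression
    profile: columns tau, H_bits, entropy_score, n_groups, scoreable."""
    p = squared_probability(profile)
    H, score = entropy_score(p)
    t = tau(p)
    scoreable = ~np.isnan(np.atleast_2d(p)).any(axis=1)
    idx = profile.index if isinstance(profile, pd.DataFrame) else None
    return pd.DataFrame(
        {
            "tau": np.atleast_1d(t),
            "H_bits": np.atleast_1d(H),
            "entropy_score": np.atleast_1d(score),
            "n_groups": np.asarray(profile).shape[1],
            "scoreable": scoreable,
        },
        index=idx,
    )


def calibrate_entropy_threshold(scores: pd.DataFrame, tau_star: float = 0.85,
                                min_genes: int = 10) -> ThresholdPair:
    """Fit ``entropy_score = a + b ln(tau)`` over scoreable genes with
    tau > 0 and evaluate it at ``tau_star`` (clamped to [0, 1])."""
    use = scores[(scores.get("scoreable", True) != False) & (scores["tau"] > 0)]
    if len(use) < min_genes:
        raise ValueError(
            f"calibration needs at least {min_genes} genes with tau > 0 "
            f"(got {len(use)})"
        )
    x = np.log(use["tau"].to_numpy())
    y = use["entropy_score"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: all tau values identical")
    b, a = np.polyfit(x, y, 1)
    entropy_star = float(np.clip(a + b * np.log(tau_star), 0.0, 1.0))
    return ThresholdPair(tau_star=float(tau_star), entropy_star=entropy_star,
                         fit_params=(float(a), float(b)))


def classify_tra(scores: pd.DataFrame, thresholds: ThresholdPair) -> pd.DataFrame:
    """Per-gene TRA calls: a gene is a TRA if it passes the Tau threshold
    *or* the calibrated entropy-score threshold (both inclusive).
    Unscoreable genes are never TRAs and carry ``scoreable = False``."""
    scoreable = scores.get("scoreable", pd.Series(True, index=scores.index))
    passed_tau = (scores["tau"] >= thresholds.tau_star) & scoreable
    passed_entropy = (scores["entropy_score"] >= thresholds.entropy_star) & scoreable
    return pd.DataFrame(
        {
            "passed_tau": passed_tau.fillna(False),
            "passed_entropy": passed_entropy.fillna(False),
            "is_tra": (passed_tau | passed_entropy).fillna(False),
            "scoreable": scoreable,
        },
        index=scores.index,
    )


class TRAClassifier(BaseEstimator):
    """Score gene restriction across groups and call TRAs.

    Parameters
    ----------
    tau_star : float, default 0.85
        Tau threshold; 0.85, 0.9 and 0.95 are the standard operating points.
    min_genes_for_fit : int, default 10
        Minimum scoreable genes with tau > 0 required for calibration.
    tau_on_raw_means : bool, default False
        Compute Tau on the raw group means instead of the squared-probability
        vector (comparison mode; entropy always uses the probability vector).

    Attributes
    ----------
    profile_ : DataFrame, genes x groups mean normalized expression.
    scores_ : DataFrame with tau, H_bits, entropy_score per gene.
    threshold_ : ThresholdPair with the calibrated entropy threshold.
    calls_ : DataFrame with passed_tau / passed_entropy / is_tra per gene.
    """

    def __init__(self, tau_star: float = 0.85, min_genes_for_fit: int = 10,
                 tau_on_raw_means: bool = False):
        self.tau_star = tau_star
        self.min_genes_for_fit = min_genes_for_fit
        self.tau_on_raw_means = tau_on_raw_means

    def fit(self, X, y=None):
        """Fit from normalized expression ``X`` (cells x genes or AnnData)
        and per-cell group labels ``y``; or pass a precomputed genes x
        groups profile as ``X`` with ``y=None``."""
        if y is not None:
            profile = group_mean_profile(X, y)
        elif isinstance(X, pd.DataFrame):
            profile = X
        else:
            raise ValueError("pass (expression, labels) or a profile DataFrame")
        if profile.shape[1] < 2:
            raise ValueError("at least 2 groups are required")
        self.profile_ = profile
        self.scores_ = score_specificity(profile)
        if self.tau_on_raw_means:
            m = np.asarray(profile, dtype=float)
            denom = m.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                raw_p = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), np.nan)
            self.scores_["tau"] = np.atleast_1d(tau(raw_p))
        n_unscoreable = int((~self.scores_["scoreable"]).sum())
        if n_unscoreable:
            warnings.warn(f"{n_unscoreable} all-zero genes are unscoreable")
        self.threshold_ = calibrate_entropy_threshold(
            self.scores_, self.tau_star, self.min_genes_for_fit
        )
        self.calls_ = classify_tra(self.scores_, self.threshold_)
        return self

    def predict(self, X=None, y=None) -> np.ndarray:
        """Boolean TRA call per gene; with arguments, scores new data
        against the fitted thresholds."""
        if X is None:
            return self.calls_["is_tra"].to_numpy()
        profile = group_mean_profile(X, y) if y is not None else X
        scores = score_specificity(profile)
        return classify_tra(scores, self.threshold_)["is_tra"].to_numpy()
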