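"""Consensus differential expression across replicate contrasts.

The procedure, per cell type with enough cells in every sample:

1.  per-gene statistics for each replicate KO-vs-WT contrast (and for the
    WT-vs-WT / KO-vs-KO batch-control contrasts): mean log2 fold change,
    a bootstrap Bayes factor, nonzero-expression fractions and the 99th
    percentile ("peak") normalized expression;
2.  a threshold filter (three preset variants mirroring the
    genotype-contrast, subcluster-marker and mimetic-vs-rest analyses);
3.  consensus: a (gene, cell type) call is kept only if present with a
    consistent direction in *every* replicate contrast and absent from all
    batch-control contrasts;
4.  a volcano collapse reporting, per gene, the record with the largest
    |log2 fold change| across cell types.

The built-in Bayes-factor estimator is a bootstrap stand-in contract:
with q the bootstrap probability (resampling cells within each group)
that the log fold change has the same sign as the point estimate, the
Bayes factor is ln(q / (1 - q)), q clipped away from 0 and 1.  Externally
computed per-gene statistic tables are accepted anywhere a stats table is.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .preprocessing import normalize

__all__ = [
    "DEThresholds",
    "GENOTYPE_THRESHOLDS",
    "MARKER_THRESHOLDS",
    "MIMETIC_THRESHOLDS",
    "eligible_cell_types",
    "estimate_gene_stats",
    "apply_de_filter",
    "consensus_across_replicates",
    "collapse_for_volcano",
    "count_directions",
    "ConsensusDE",
]


@dataclass
class DEThresholds:
    """Cutoffs of the DE filter.

    ``bf_min``, ``lfc_abs_min`` and ``peak_min`` are strict ("over");
    ``frac_min`` is inclusive ("at least").  ``peak_min=None`` disables the
    peak-expression rule.  ``frac_mode`` selects which nonzero fraction the
    5/10% rule reads: "max" (either group suffices, symmetric genotype
    contrast) or "A" (the group of interest, marker variants).
    """

    bf_min: float = 2.5
    lfc_abs_min: float = 1.0
    frac_min: float = 0.05
    peak_min: float | None = 0.5
    frac_mode: str = "max"

    def __post_init__(self) -> None:
        for name in ("bf_min", "lfc_abs_min", "frac_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.peak_min is not None and self.peak_min < 0:
            raise ValueError("peak_min must be >= 0")
        if self.frac_mode not in ("max", "A"):
            raise ValueError("frac_mode must be 'max' or 'A'")


GENOTYPE_THRESHOLDS = DEThresholds(bf_min=2.5, lfc_abs_min=1.0, frac_min=0.05,
                                   peak_min=0.5, frac_mode="max")
MARKER_THRESHOLDS = DEThresholds(bf_min=3.0, lfc_abs_min=1.0, frac_min=0.10,
                                 peak_min=None, frac_mode="A")
MIMETIC_THRESHOLDS = DEThresholds(bf_min=2.5, lfc_abs_min=1.0, frac_min=0.10,
                                  peak_min=None, frac_mode="A")
_VARIANTS = {"genotype": GENOTYPE_THRESHOLDS, "marker": MARKER_THRESHOLDS,
             "mimetic": MIMETIC_THRESHOLDS}


def eligible_cell_types(cells: pd.DataFrame, min_cells: int = 30,
                        celltype_col: str = "cell_type",
                        sample_col: str = "sample_id",
                        samples=None) -> list:
    """Cell types with at least ``min_cells`` cells in every sample
    participating in the contrast (all samples by default)."""
    for col in (celltype_col, sample_col):
        if col not in cells:
            raise ValueError(f"cell table misses column {col!r}")
    tab = pd.crosstab(cells[celltype_col], cells[sample_col])
    if samples is not None:
        missing = [s for s in samples if s not in tab.columns]
        for s in missing:
            tab[s] = 0
        tab = tab[list(samples)]
    ok = (tab >= min_cells).all(axis=1)
    return [ct for ct in tab.index[ok]]


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)


def estimate_gene_stats(norm_A, norm_B, raw_A=None, raw_B=None,
                        gene_names=None, n_boot: int = 500, seed: int = 0,
                        epsilon: float = 1e-4) -> pd.DataFrame:
    """Per-gene contrast statistics for group A over group B.

    ``norm_A``/``norm_B`` are linear normalized expression (cells x genes);
    ``raw_A``/``raw_B`` optionally supply the raw counts used for the
    nonzero fractions (the normalized matrices are used when omitted —
    identical zero patterns).  Deterministic for a fixed seed.
    """
    A, B = _dense(norm_A), _dense(norm_B)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("both groups must be nonempty")
    rA = _dense(raw_A) if raw_A is not None else A
    rB = _dense(raw_B) if raw_B is not None else B

    mean_A, mean_B = A.mean(axis=0), B.mean(axis=0)
    lfc = np.log2((mean_A + epsilon) / (mean_B + epsilon))
    frac_A, frac_B = (rA > 0).mean(axis=0), (rB > 0).mean(axis=0)
    peak = np.percentile(np.vstack([A, B]), 99, axis=0)

    rng = np.random.default_rng(seed)
    nA, nB = A.shape[0], B.shape[0]
    WA = rng.multinomial(nA, np.full(nA, 1.0 / nA), size=n_boot)
    WB = rng.multinomial(nB, np.full(nB, 1.0 / nB), size=n_boot)
    boot_lfc = np.log2((WA @ A / nA + epsilon) / (WB @ B / nB + epsilon))
    sign = np.sign(lfc)
    q = np.where(sign == 0, 0.5,
                 (np.sign(boot_lfc) == sign).mean(axis=0))
    q = np.clip(q, 1.0 / (n_boot + 1), n_boot / (n_boot + 1))
    bf = np.log(q / (1.0 - q))

    if gene_names is None:
        gene_names = [f"g{i}" for i in range(A.shape[1])]
    return pd.DataFrame(
        {
            "gene": np.asarray(gene_names),
            "bayes_factor": bf,
            "lfc_mean": lfc,
            "frac_nonzero_a": frac_A,
            "frac_nonzero_b": frac_B,
            "peak_expr": peak,
            "mean_a": mean_A,
            "mean_b": mean_B,
        }
    )


def apply_de_filter(stats: pd.DataFrame, thresholds: DEThresholds) -> pd.DataFrame:
    """Rows of ``stats`` passing every threshold, with a direction column.

    Pass rule: bayes_factor > bf_min AND |lfc_mean| > lfc_abs_min AND
    nonzero fraction >= frac_min AND (peak_expr > peak_min when enabled).
    """
    required = ["bayes_factor", "lfc_mean", "frac_nonzero_a"]
    if thresholds.frac_mode == "max":
        required.append("frac_nonzero_b")
    if thresholds.peak_min is not None:
        required.append("peak_expr")
    for col in required:
        if col not in stats:
            raise ValueError(f"stats table misses required column {col!r}")
    frac = (np.maximum(stats["frac_nonzero_a"], stats["frac_nonzero_b"])
            if thresholds.frac_mode == "max" else stats["frac_nonzero_a"])
    mask = (
        (stats["bayes_factor"] > thresholds.bf_min)
        & (stats["lfc_mean"].abs() > thresholds.lfc_abs_min)
        & (frac >= thresholds.frac_min)
    )
    if thresholds.peak_min is not None:
        mask &= stats["peak_expr"] > thresholds.peak_min
    calls = stats.loc[mask].copy()
    calls["direction"] = np.where(calls["lfc_mean"] > 0, "up", "down")
    return calls.reset_index(drop=True)


def consensus_across_replicates(replicate_calls: list[pd.DataFrame],
                                batch_calls: list[pd.DataFrame] | None = None,
                                keys: tuple[str, ...] = ("gene", "cell_type"),
                                ) -> pd.DataFrame:
    """Intersect replicate call sets, drop direction conflicts and
    batch-control hits.

    A key (gene, cell type by default) survives only if it is called in
    every replicate contrast with one consistent direction and appears in
    no batch-control call set.  The returned frame carries the first
    replicate contrast's statistics.
    """
    if not replicate_calls:
        raise ValueError("at least one replicate contrast is required")
    keys = list(keys)

    def _key_index(df: pd.DataFrame) -> pd.Index:
        return pd.MultiIndex.from_frame(df[keys]) if len(keys) > 1 \
            else pd.Index(df[keys[0]])

    common = _key_index(replicate_calls[0])
    for df in replicate_calls[1:]:
        common = common.intersection(_key_index(df))

    # direction consistency across all replicate contrasts
    directions = []
    for df in replicate_calls:
        d = df.set_index(_key_index(df))["direction"]
        directions.append(d.loc[common])
    consistent = np.ones(len(common), dtype=bool)
    for d in directions[1:]:
        consistent &= (d.to_numpy() == directions[0].to_numpy())
    common = common[consistent]

    for df in batch_calls or []:
        common = common.difference(_key_index(df))

    first = replicate_calls[0].set_index(_key_index(replicate_calls[0]))
    out = first.loc[common].reset_index(drop=True)
    return out.sort_values(keys).reset_index(drop=True)


def collapse_for_volcano(calls: pd.DataFrame) -> pd.DataFrame:
    """One record per gene for volcano display: the cell type's record with
    maximal |lfc_mean|; ties broken by higher Bayes factor, then by
    lexicographic cell type."""
    if calls.empty:
        return calls.copy()
    df = calls.copy()
    df["_abs_lfc"] = df["lfc_mean"].abs()
    df = df.sort_values(["_abs_lfc", "bayes_factor", "cell_type"],
                        ascending=[False, False, True], kind="mergesort")
    out = df.drop_duplicates("gene", keep="first").drop(columns="_abs_lfc")
    return out.sort_values("gene").reset_index(drop=True)


def count_directions(calls: pd.DataFrame) -> tuple[int, int]:
    """(n_up, n_down) tallies over a call set's direction column."""
    if calls is None or calls.empty:
        return (0, 0)
    vals = calls["direction"].to_numpy()
    return int((vals == "up").sum()), int((vals == "down").sum())


class ConsensusDE(BaseEstimator):
    """End-to-end consensus differential expression on an AnnData of raw
    counts with sample/genotype/replicate/cell-type metadata.

    Replicate contrasts pair test-genotype and reference replicates
    positionally (KO_r vs WT_r); batch-control contrasts are all replicate
    pairs within each genotype.  ``direction`` in the results is the sign
    of the KO-over-WT fold change; ``tf_effect`` translates it to the
    transcription factor's action (induced = lower in the KO).

    Attributes (after ``fit``): ``eligible_cell_types_``, ``stats_``,
    ``replicate_calls_``, ``batch_calls_``, ``final_calls_``, ``volcano_``.
    """

    def __init__(self, variant: str = "genotype", reference: str = "WT",
                 test: str | None = None, min_cells: int = 30,
                 n_boot: int = 500, epsilon: float = 1e-4, seed: int = 0,
                 thresholds: DEThresholds | None = None,
                 target_sum: float = 10_000.0,
                 sample_col: str = "sample_id", genotype_col: str = "genotype",
                 replicate_col: str = "replicate",
                 celltype_col: str = "cell_type"):
        self.variant = variant
        self.reference = reference
        self.test = test
        self.min_cells = min_cells
        self.n_boot = n_boot
        self.epsilon = epsilon
        self.seed = seed
        self.thresholds = thresholds
        self.target_sum = target_sum
        self.sample_col = sample_col
        self.genotype_col = genotype_col
        self.replicate_col = replicate_col
        self.celltype_col = celltype_col

    def _thresholds(self) -> DEThresholds:
        if self.thresholds is not None:
            return self.thresholds
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        return replace(_VARIANTS[self.variant])

    def fit(self, adata: ad.AnnData, y=None):
        obs = adata.obs
        genotypes = obs[self.genotype_col].astype(str)
        if self.test is None:
            others = sorted(set(genotypes) - {self.reference})
            if len(others) != 1:
                raise ValueError(f"test genotype ambiguous among {others}")
            test = others[0]
        else:
            test = self.test
        if self.reference not in set(genotypes):
            raise ValueError(f"reference genotype {self.reference!r} not present")

        reps_ref = sorted(obs.loc[genotypes == self.reference, self.replicate_col].unique())
        reps_test = sorted(obs.loc[genotypes == test, self.replicate_col].unique())
        if len(reps_ref) != len(reps_test):
            raise ValueError("replicate counts differ between genotypes; "
                             "pair replicates manually via estimate_gene_stats")
        if len(reps_ref) < 2:
            raise ValueError("at least 2 replicate contrasts are required")

        norm = normalize(adata, target_sum=self.target_sum, log1p=False)
        Xn, Xr = norm.X, adata.X
        thresholds = self._thresholds()
        self.eligible_cell_types_ = eligible_cell_types(
            obs, self.min_cells, self.celltype_col, self.sample_col
        )

        def _mask(genotype, rep, ct):
            return ((genotypes == genotype) & (obs[self.replicate_col] == rep)
                    & (obs[self.celltype_col].astype(str) == str(ct))).to_numpy()

        stats_rows, rep_calls, batch_calls = [], {}, []
        contrast_seed = np.random.SeedSequence(self.seed).generate_state(1)[0] % (2**31)
        k = 0
        for ct in self.eligible_cell_types_:
            per_rep = []
            for r_test, r_ref in zip(reps_test, reps_ref):
                mA, mB = _mask(test, r_test, ct), _mask(self.reference, r_ref, ct)
                st = estimate_gene_stats(
                    Xn[mA], Xn[mB], Xr[mA], Xr[mB],
                    gene_names=adata.var_names, n_boot=self.n_boot,
                    seed=(contrast_seed + k) % (2**31), epsilon=self.epsilon,
                )
                k += 1
                st["cell_type"] = ct
                st["contrast"] = f"{test}_r{r_test}_vs_{self.reference}_r{r_ref}"
                stats_rows.append(st)
                per_rep.append(apply_de_filter(st, thresholds))
            rep_calls[ct] = per_rep
            for genotype, reps in ((self.reference, reps_ref), (test, reps_test)):
                for i in range(len(reps)):
                    for j in range(i + 1, len(reps)):
                        mA, mB = _mask(genotype, reps[i], ct), _mask(genotype, reps[j], ct)
                        st = estimate_gene_stats(
                            Xn[mA], Xn[mB], Xr[mA], Xr[mB],
                            gene_names=adata.var_names, n_boot=self.n_boot,
                            seed=(contrast_seed + k) % (2**31), epsilon=self.epsilon,
                        )
                        k += 1
                        st["cell_type"] = ct
                        st["contrast"] = f"{genotype}_r{reps[i]}_vs_r{reps[j]}"
                        stats_rows.append(st)
                        batch_calls.append(apply_de_filter(st, thresholds))

        self.stats_ = (pd.concat(stats_rows, ignore_index=True)
                       if stats_rows else pd.DataFrame())
        self.replicate_calls_ = rep_calls
        self.batch_calls_ = batch_calls
        finals = []
        for ct, per_rep in rep_calls.items():
            batch_ct = [b[b["cell_type"] == ct] for b in batch_calls]
            finals.append(consensus_across_replicates(per_rep, batch_ct))
        self.final_calls_ = (pd.concat(finals, ignore_index=True)
                             if finals else pd.DataFrame())
        if not self.final_calls_.empty:
            self.final_calls_["tf_effect"] = np.where(
                self.final_calls_["direction"] == "down", "induced", "repressed"
            )
            self.volcano_ = collapse_for_volcano(self.final_calls_)
        else:
            self.volcano_ = self.final_calls_.copy()
        return self
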