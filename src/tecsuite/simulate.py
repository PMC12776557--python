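"""Planted-truth count simulators.

Two generators cover the statistical structure the downstream analyses
assume:

``simulate_atlas``
    A multi-cell-type "tissue atlas": every gene is expressed ("on") in a
    controlled number of cell types (its *breadth*) and near-silent
    elsewhere.  Genes of breadth one or two are tissue-restricted antigens
    (TRAs) by construction, which gives specificity scoring a ground truth.

``simulate_tec_experiment``
    A multi-replicate WT/KO experiment: per-sample cell-type composition is
    drawn multinomially from genotype-specific proportions, regulated genes
    are shifted multiplicatively (mean x 2**effect) in the non-reference
    genotype, batch genes receive replicate-specific offsets in *all*
    genotypes, and each cell gets 2D embedding coordinates from per-type
    Gaussians.  Composition shifts, regulated programs and batch genes are
    all recorded as ground truth.

Counts are negative binomial with mean ``mu`` and inverse-dispersion
``theta`` (variance ``mu + mu**2/theta``); ``dispersion=None`` selects the
Poisson limit.  Each cell type (atlas) or sample (experiment) draws from its
own RNG stream spawned from the master seed, so adding a sample never
perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "AtlasSpec",
    "ExperimentSpec",
    "RegulatedGene",
    "GroundTruth",
    "simulate_atlas",
    "simulate_tec_experiment",
]


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float | None) -> np.ndarray:
    """Negative binomial draw with mean/inverse-dispersion parameterization."""
    mean = np.asarray(mean, dtype=float)
    if dispersion is None or not np.isfinite(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated dataset.

    Attributes are filled depending on the generator: the atlas sets
    ``tra_labels``/``breadth``/``detectable``; the experiment sets
    ``regulated_calls``, ``batch_genes`` and ``composition_log2fc``.
    """

    tra_labels: pd.Series | None = None
    breadth: pd.Series | None = None
    detectable: pd.Series | None = None
    regulated_calls: pd.DataFrame | None = None
    batch_genes: list[str] = field(default_factory=list)
    composition_log2fc: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

@dataclass
class AtlasSpec:
    """Parameters of the multi-cell-type atlas generator.

    Parameters
    ----------
    n_cell_types, n_cells_per_type, n_genes
        Atlas dimensions.
    restriction_plan
        Per-gene breadth (number of cell types in which the gene is "on"),
        each in ``1..n_cell_types``.  When ``None`` a default plan is built:
        ``frac_restricted`` of genes at ``restricted_breadth``, the rest
        broad with breadth uniform in ``[ceil(n/2), n]``.
    on_mean, off_mean
        Expected counts per cell in on/off cell types (``on_mean >=
        off_mean >= 0``).
    dispersion
        Negative-binomial inverse dispersion (> 0); ``None`` for Poisson.
    tra_breadth_max
        Genes with breadth at or below this are labelled TRA in the truth.
    frac_noncoding
        Fraction of genes annotated with a non-protein-coding biotype.
    """

    n_cell_types: int = 20
    n_cells_per_type: int = 200
    n_genes: int = 2000
    restriction_plan: np.ndarray | None = None
    frac_restricted: float = 0.10
    restricted_breadth: int = 1
    on_mean: float = 5.0
    off_mean: float = 0.1
    dispersion: float | None = 2.0
    tra_breadth_max: int = 2
    frac_noncoding: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cell_types", "n_cells_per_type", "n_genes"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_cell_types < 2:
            raise ValueError("n_cell_types must be >= 2 for specificity scoring")
        if not (0.0 <= self.off_mean <= self.on_mean):
            raise ValueError("require on_mean >= off_mean >= 0")
        if self.dispersion is not None and not self.dispersion > 0:
            raise ValueError("dispersion must be > 0 (or None for Poisson)")
        if self.restriction_plan is not None:
            plan = np.asarray(self.restriction_plan)
            if plan.shape != (self.n_genes,):
                raise ValueError("restriction_plan must have one breadth per gene")
            if plan.min() < 1 or plan.max() > self.n_cell_types:
                raise ValueError(
                    "restriction_plan breadths must lie in [1, n_cell_types]"
                )
        if not 0.0 <= self.frac_restricted <= 1.0:
            raise ValueError("frac_restricted must lie in [0, 1]")
        if not 0.0 <= self.frac_noncoding <= 1.0:
            raise ValueError("frac_noncoding must lie in [0, 1]")


def _default_plan(spec: AtlasSpec, rng: np.random.Generator) -> np.ndarray:
    n_restricted = int(round(spec.frac_restricted * spec.n_genes))
    plan = np.empty(spec.n_genes, dtype=int)
    plan[:n_restricted] = spec.restricted_breadth
    lo = math.ceil(spec.n_cell_types / 2)
    plan[n_restricted:] = rng.integers(lo, spec.n_cell_types + 1,
                                       size=spec.n_genes - n_restricted)
    return plan


def simulate_atlas(spec: AtlasSpec) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a multi-cell-type atlas with planted gene restriction breadths.

    Returns an :class:`~anndata.AnnData` (X: sparse integer counts, obs:
    ``cell_type``, var: ``biotype``/``breadth``/``true_tra``) and the
    matching :class:`GroundTruth`.  Reproducible for a fixed seed.
    """
    spec.validate()
    master = np.random.default_rng(spec.seed)
    plan = (np.asarray(spec.restriction_plan, dtype=int)
            if spec.restriction_plan is not None else _default_plan(spec, master))

    genes = np.array([f"gene{i:05d}" for i in range(spec.n_genes)])
    # which cell types each gene is "on" in
    mean_matrix = np.full((spec.n_genes, spec.n_cell_types), spec.off_mean)
    for g in range(spec.n_genes):
        on = master.choice(spec.n_cell_types, size=plan[g], replace=False)
        mean_matrix[g, on] = spec.on_mean

    blocks, labels = [], []
    for t in range(spec.n_cell_types):
        rng_t = np.random.default_rng([spec.seed, t])
        mu = np.broadcast_to(mean_matrix[:, t], (spec.n_cells_per_type, spec.n_genes))
        blocks.append(sp.csr_matrix(_nb_sample(rng_t, mu, spec.dispersion)))
        labels.extend([f"type{t:02d}"] * spec.n_cells_per_type)

    X = sp.vstack(blocks, format="csr")
    n_cells = X.shape[0]
    obs = pd.DataFrame(
        {"cell_type": pd.Categorical(labels)},
        index=[f"cell{i:06d}" for i in range(n_cells)],
    )
    biotype = np.where(
        master.random(spec.n_genes) < spec.frac_noncoding, "lincRNA", "protein_coding"
    )
    detectable = mean_matrix.max(axis=1) > 0
    true_tra = (plan <= spec.tra_breadth_max) & detectable
    var = pd.DataFrame(
        {"biotype": biotype, "breadth": plan, "true_tra": true_tra},
        index=genes,
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.varm["planted_mean"] = mean_matrix  # genes x cell types, type order
    truth = GroundTruth(
        tra_labels=pd.Series(true_tra, index=genes),
        breadth=pd.Series(plan, index=genes),
        detectable=pd.Series(detectable, index=genes),
    )
    return adata, truth


# ---------------------------------------------------------------------------
# WT/KO experiment
# ---------------------------------------------------------------------------

@dataclass
class RegulatedGene:
    """A planted regulated gene: direction is the effect of the *factor*
    (induced = lower in the KO), ``lfc`` its log2 magnitude (> 0), and
    ``cell_types`` the affected subset (``None`` = all)."""

    gene: str
    direction: str  # "induced" | "repressed"
    lfc: float
    cell_types: tuple[str, ...] | None = None


@dataclass
class ExperimentSpec:
    """Parameters of the WT/KO experiment generator.

    ``composition`` maps each genotype to a probability vector over
    ``cell_types`` (must sum to 1).  Regulated genes may be given explicitly
    (``regulated``) or planted automatically (``n_induced``/``n_repressed``
    at ``regulated_lfc``); batch genes likewise (``n_batch_genes`` at
    ``batch_lfc``).  ``doublet_frac``/``damaged_frac`` plant QC true
    positives: doublets get doubled totals and a high doublet score, damaged
    cells an elevated mitochondrial share.
    """

    genotypes: tuple[str, ...] = ("WT", "KO")
    reference: str = "WT"
    replicates_per_genotype: int = 2
    cell_types: tuple[str, ...] = ("mTEC-A", "mTEC-B", "mTEC-C")
    composition: dict[str, Sequence[float]] | None = None
    n_cells_per_sample: int = 1500
    n_genes: int = 1000
    base_mean_sigma: float = 1.0
    dispersion: float | None = 2.0
    regulated: list[RegulatedGene] | None = None
    n_induced: int = 0
    n_repressed: int = 0
    regulated_lfc: float = 2.0
    regulated_cell_types: tuple[str, ...] | None = None
    batch_genes: list[str] | None = None
    n_batch_genes: int = 0
    batch_lfc: float = 1.5
    min_regulated_base_mean: float = 0.5
    embedding_centers: np.ndarray | None = None
    embedding_spread: float = 1.0
    n_mito_genes: int = 5
    mito_share: float = 0.02
    damaged_mito_share: float = 0.15
    doublet_frac: float = 0.0
    damaged_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.reference not in self.genotypes:
            raise ValueError(
                f"reference genotype {self.reference!r} absent from genotypes"
            )
        if len(self.genotypes) < 2:
            raise ValueError("genotypes must contain at least two conditions")
        if self.replicates_per_genotype < 1:
            raise ValueError("replicates_per_genotype must be positive")
        if self.n_cells_per_sample < 1 or self.n_genes < 1:
            raise ValueError("n_cells_per_sample and n_genes must be positive")
        comp = self.composition or {}
        for gt in self.genotypes:
            vec = np.asarray(comp.get(gt, self._uniform()), dtype=float)
            if vec.shape != (len(self.cell_types),):
                raise ValueError(f"composition[{gt!r}] has wrong length")
            if abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"composition[{gt!r}] must sum to 1")
            if (vec < 0).any():
                raise ValueError(f"composition[{gt!r}] has negative entries")
        if self.regulated is not None:
            for r in self.regulated:
                if r.direction not in ("induced", "repressed"):
                    raise ValueError(f"regulated gene {r.gene}: bad direction {r.direction!r}")
                if not r.lfc > 0:
                    raise ValueError(f"regulated gene {r.gene}: effect magnitude must be nonzero")
        if not 0 <= self.doublet_frac < 1 or not 0 <= self.damaged_frac < 1:
            raise ValueError("doublet_frac and damaged_frac must lie in [0, 1)")

    def _uniform(self) -> np.ndarray:
        k = len(self.cell_types)
        return np.full(k, 1.0 / k)

    def composition_of(self, genotype: str) -> np.ndarray:
        comp = self.composition or {}
        return np.asarray(comp.get(genotype, self._uniform()), dtype=float)


def _pick_programs(spec: ExperimentSpec, genes: np.ndarray, base_means: np.ndarray,
                   rng: np.random.Generator) -> tuple[list[RegulatedGene], list[str]]:
    regulated = list(spec.regulated) if spec.regulated is not None else []
    batch = list(spec.batch_genes) if spec.batch_genes is not None else []
    need = (spec.regulated is None and (spec.n_induced or spec.n_repressed))
    need_batch = spec.batch_genes is None and spec.n_batch_genes
    if need or need_batch:
        eligible = np.flatnonzero(
            (base_means >= spec.min_regulated_base_mean)
            & ~np.char.startswith(genes.astype(str), "mt-")
        )
        n_want = (spec.n_induced + spec.n_repressed if need else 0) + (
            spec.n_batch_genes if need_batch else 0
        )
        if len(eligible) < n_want:
            raise ValueError(
                "not enough genes above min_regulated_base_mean to plant programs"
            )
        chosen = rng.choice(eligible, size=n_want, replace=False)
        k = 0
        if need:
            for _ in range(spec.n_induced):
                regulated.append(RegulatedGene(genes[chosen[k]], "induced",
                                               spec.regulated_lfc,
                                               spec.regulated_cell_types))
                k += 1
            for _ in range(spec.n_repressed):
                regulated.append(RegulatedGene(genes[chosen[k]], "repressed",
                                               spec.regulated_lfc,
                                               spec.regulated_cell_types))
                k += 1
        if need_batch:
            batch = [genes[i] for i in chosen[k:]]
    return regulated, batch


def simulate_tec_experiment(spec: ExperimentSpec) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a replicated WT/KO experiment with planted composition shifts,
    regulated programs and batch genes.

    Per sample, cell-type counts are multinomial from the genotype's
    composition; regulated genes shift the mean by ``2**(+-lfc)`` in
    non-reference genotypes (induced genes are *lower* in the KO); batch
    genes shift per replicate index in all genotypes; 2D coordinates come
    from per-type Gaussians.  Deterministic for a fixed seed.
    """
    spec.validate()
    master = np.random.default_rng(spec.seed)
    k_types = len(spec.cell_types)

    genes = np.array(
        [f"mt-g{i}" for i in range(spec.n_mito_genes)]
        + [f"gene{i:05d}" for i in range(spec.n_genes - spec.n_mito_genes)]
    )
    is_mito = np.char.startswith(genes.astype(str), "mt-")
    base_means = master.lognormal(mean=0.0, sigma=spec.base_mean_sigma,
                                  size=spec.n_genes)
    # rescale mito genes so their expected share of counts is mito_share
    if spec.n_mito_genes and spec.mito_share > 0:
        other = base_means[~is_mito].sum()
        target = spec.mito_share / (1 - spec.mito_share) * other
        base_means[is_mito] *= target / base_means[is_mito].sum()

    regulated, batch_genes = _pick_programs(spec, genes, base_means, master)
    gene_index = {g: i for i, g in enumerate(genes)}

    # per cell type x gene log2 effect in non-reference genotypes
    effect = np.zeros((k_types, spec.n_genes))
    reg_rows = []
    for r in regulated:
        sign = -1.0 if r.direction == "induced" else 1.0
        types = r.cell_types if r.cell_types is not None else spec.cell_types
        for ct in types:
            effect[spec.cell_types.index(ct), gene_index[r.gene]] = sign * r.lfc
        reg_rows.append({"gene": r.gene, "direction": r.direction, "lfc": r.lfc,
                         "cell_types": ",".join(types)})

    R = spec.replicates_per_genotype
    if R > 1:
        batch_offsets = np.linspace(-1.0, 1.0, R) * spec.batch_lfc
    else:
        batch_offsets = np.zeros(1)
    batch_idx = np.array([gene_index[g] for g in batch_genes], dtype=int)

    if spec.embedding_centers is not None:
        centers = np.asarray(spec.embedding_centers, dtype=float)
    else:
        ang = 2 * np.pi * np.arange(k_types) / k_types
        centers = 10.0 * np.column_stack([np.cos(ang), np.sin(ang)])

    blocks, obs_rows = [], []
    sample_idx = 0
    for genotype in spec.genotypes:
        comp = spec.composition_of(genotype)
        for rep in range(R):
            rng = np.random.default_rng([spec.seed, sample_idx])
            sample_id = f"{genotype}_r{rep + 1}"
            type_counts = rng.multinomial(spec.n_cells_per_sample, comp)
            for t, n_t in enumerate(type_counts):
                if n_t == 0:
                    continue
                mu = base_means.copy()
                if genotype != spec.reference:
                    mu = mu * np.exp2(effect[t])
                if batch_idx.size:
                    mu[batch_idx] = mu[batch_idx] * 2.0 ** batch_offsets[rep]
                mu_cells = np.broadcast_to(mu, (n_t, spec.n_genes)).copy()

                is_doublet = rng.random(n_t) < spec.doublet_frac
                is_damaged = (~is_doublet) & (rng.random(n_t) < spec.damaged_frac)
                mu_cells[is_doublet] *= 2.0
                if is_damaged.any() and is_mito.any():
                    non_mito_total = mu[~is_mito].sum()
                    dam_target = (spec.damaged_mito_share
                                  / (1 - spec.damaged_mito_share) * non_mito_total)
                    scale = dam_target / max(mu[is_mito].sum(), 1e-12)
                    mu_cells[np.ix_(is_damaged, is_mito)] *= scale

                counts = _nb_sample(rng, mu_cells, spec.dispersion)
                blocks.append(sp.csr_matrix(counts))
                coords = centers[t] + spec.embedding_spread * rng.standard_normal((n_t, 2))
                score = np.where(is_doublet, rng.uniform(0.25, 0.6, n_t),
                                 rng.uniform(0.0, 0.15, n_t))
                for j in range(n_t):
                    obs_rows.append({
                        "sample_id": sample_id, "genotype": genotype,
                        "replicate": rep + 1, "cell_type": spec.cell_types[t],
                        "umap1": coords[j, 0], "umap2": coords[j, 1],
                        "doublet_score": score[j],
                        "is_doublet": bool(is_doublet[j]),
                        "is_damaged": bool(is_damaged[j]),
                    })
            sample_idx += 1

    X = sp.vstack(blocks, format="csr")
    obs = pd.DataFrame(obs_rows, index=[f"cell{i:06d}" for i in range(X.shape[0])])
    for col in ("sample_id", "genotype", "cell_type"):
        obs[col] = pd.Categorical(obs[col])
    var = pd.DataFrame(
        {"biotype": "protein_coding", "base_mean": base_means,
         "is_batch_gene": np.isin(genes, batch_genes)},
        index=genes,
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)

    ref_comp = spec.composition_of(spec.reference)
    comp_fc = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for gt in spec.genotypes:
            if gt == spec.reference:
                continue
            comp_fc[gt] = np.log2(spec.composition_of(gt) / ref_comp)
    truth = GroundTruth(
        regulated_calls=pd.DataFrame(
            reg_rows, columns=["gene", "direction", "lfc", "cell_types"]
        ),
        batch_genes=list(batch_genes),
        composition_log2fc=pd.DataFrame(comp_fc, index=list(spec.cell_types)),
    )
    return adata, truth
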