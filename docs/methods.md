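# Methods

This note records the models, conventions and numerical choices behind
each component, what the simulators do and do not emulate, and the design
decisions taken where more than one reading was defensible.

## Count model and simulators

Counts are negative binomial, parameterized by mean μ and
inverse-dispersion θ (variance μ + μ²/θ); `dispersion=None` selects the
Poisson limit θ → ∞. This is the standard overdispersed model for UMI
counts; θ = 2 is the default, a moderately overdispersed regime typical
of droplet data. Each cell type (atlas) or sample (experiment) draws from
its own RNG stream spawned as `default_rng([seed, index])`, so adding a
sample or changing one genotype's composition never perturbs the draws of
the others — a property the tests rely on.

**Atlas generator.** Every gene is "on" (mean `on_mean`, default 5
counts/cell) in a planted number of cell types — its breadth — and near
silent (`off_mean`, default 0.1) elsewhere. The default restriction plan
makes 10% of genes breadth-1 and draws the remaining breadths uniformly
from [⌈n/2⌉, n]: restricted genes are unambiguous TRAs, broad genes are
unambiguous non-TRAs, and the truth label is breadth ≤ 2. The bimodal
breadth distribution is a deliberate idealization — real atlases have a
continuum of intermediate breadths, so the near-perfect recovery rates on
simulated data bound what the scorer can do when classes are separable,
not its resolution on borderline genes. `on_mean ≥ off_mean ≥ 0` is
required; a fully silent configuration is allowed and every zero-mean
gene is flagged undetectable in the ground truth.

**Experiment generator.** Per sample, cell-type counts are multinomial
from the genotype's composition vector. Baseline gene means are lognormal
(μ = 0, σ = 1, ≈ 1.6 counts/cell on average, so default cells carry a few
hundred to a few thousand UMIs). Regulated genes act multiplicatively on
the mean — mean × 2^(±LFC) in the non-reference genotype only, with
"induced by the factor" meaning *lower* in the KO — matching the log2
fold-change semantics of the DE thresholds. Batch genes are shifted per
replicate index in **all** genotypes (offsets spread over ±`batch_lfc`),
which is how a library-preparation batch shared by co-processed samples
behaves; with replicate-paired contrasts these genes surface in the
WT-vs-WT and KO-vs-KO control contrasts and must be removed by the
consensus step. Regulated and batch genes are sampled from genes with
baseline mean ≥ 0.5 counts/cell: a DE call is only meaningful for genes
that clear the detection-style filters, so planting effects on
undetectable genes would test the generator, not the pipeline. Embedding
coordinates are per-cell-type isotropic Gaussians on a circle of radius
10 (spread 1), giving well-separated clusters; no attempt is made to
mimic real UMAP topology or gene–gene correlation. Optional doublets
(doubled totals, doublet score drawn from U(0.25, 0.6) vs U(0, 0.15) for
clean cells) and damaged cells (mitochondrial share raised to 15%) give
the QC cascade true positives; both default to 0 and are enabled where QC
is under test.

## QC cascade

Stages run in a fixed order — (1) preliminary cell filter (< 100 detected
genes) then gene filter (detected in < 20 cells); (2) doublet score
> 0.2; (3) mitochondrial % > 5, UMIs outside (1,000, 70,000), detected
genes outside (1,000, 8,500) — with each removed cell attributed to the
first stage that removes it. All "over"/"less than" wordings are strict
inequalities and "at least" is inclusive: a cell at exactly 1,000 UMIs or
a doublet score of exactly 0.2 survives. Stage-3 per-cell metrics are
computed once on the matrix as it stands entering stage 3. Mitochondrial
counts use a gene-name prefix (default `mt-`) or an explicit list, since
no canonical set exists for arbitrary inputs. The cascade is one-pass; a
second application can in principle remove more genes (cells removed at
stages 2–3 can push a gene below the 20-cell rule), but on non-boundary
data the fixpoint is reached in one pass, which the idempotence test
checks on generator output.

Normalization scales each cell to 10,000 total counts on the linear
scale; all-zero cells are left zero with a warning. The optional log
transform is natural log1p and is recorded in `uns`, and downstream
functions that require linear values refuse log-transformed input. The
atlas-side detection filter (≥ 500 detected genes per cell, then ≥ 2 raw
counts in ≥ 100 cells per gene, inclusive) and display clipping to the
1st/99th percentile (linear-interpolation percentiles, pinned for
reproducibility) round out preprocessing.

## TRA scoring

Both the entropy score and τ are computed on the squared-probability
vector p, not on raw means: squaring sharpens the profile before the
probability transform, and applying both statistics to the same
distribution is the literal reading of the procedure this implements. A
flag (`tau_on_raw_means`) offers the conventional Tau-on-max-normalized
means for comparison. Entropy uses base 2 so that H/log₂ n is
dimensionless. All-zero profiles are reported unscoreable (the transform
is 0/0) rather than assigned τ = 0, and are excluded from calibration and
classification.

The calibration regresses entropy score on ln τ by least squares over
genes with τ > 0 — the direction in which evaluating the fit at a chosen
τ\* yields an entropy threshold; the fitted value is clamped to [0, 1].
The model form (a + b·ln τ) is a package design choice: it is the
simplest "logarithmic model" for which the E–τ relationship is monotone
and evaluable, and its exact-recovery behaviour on noise-free scores is
pinned by test. τ\* = 0.85 is the default operating point; 0.9 and 0.95
are presets. Threshold comparisons are inclusive (≥), and the TRA call is
the union of the two criteria — genes restricted enough to pass only one
statistic are still called.

## Differential density

Each genotype's KDE is a product-Gaussian average with per-dimension
bandwidth h_d = σ_d·(4/((d+2)m))^(1/(d+4)) (d = 2, sample SD with
ddof = 1): the textbook multivariate normal-reference rule, whose d = 2
constant is 1.0 (the popular univariate 1.06·σ·m^(−1/5) is its d = 1
case). Densities are evaluated in log space with logsumexp, so the log
ratio is finite for every cell; evaluation points are all cells of both
genotypes, matching a per-cell colored embedding. Because each
genotype's density integrates to 1, the statistic measures *relative*
composition, not absolute cell numbers; the natural-log base only
rescales the diverging colormap. More than two genotypes are handled
pairwise against the designated reference. Zero variance in a dimension
(e.g. a degenerate embedding) raises an error suggesting jitter; samples
of fewer than two cells require an explicit bandwidth.

## Consensus differential expression

The built-in per-gene statistics are a bootstrap stand-in contract, not a
reimplementation of any variational model: lfc = log₂((mean_A + ε)/(mean_B
+ ε)) with ε = 1e-4 (configurable) guarding empty means, and Bayes factor
ln(q/(1−q)) where q is the probability, over 500 within-group bootstrap
resamples (drawn as multinomial weights for speed), that the resampled
LFC keeps the point estimate's sign; q is clipped to
[1/(n_boot+1), n_boot/(n_boot+1)] and a zero LFC maps to BF = 0.
Externally computed statistic tables are accepted by every downstream
step.

Filter conventions: "over"/"greater than" strict, "at least" inclusive —
a Bayes factor of exactly 2.5 fails. The nonzero-expression fraction in
the genotype contrast uses the **maximum** of the two groups (a gene
silenced in the KO must not fail the 5% rule because of the KO group);
the marker and mimetic variants use the group of interest, where that
group is named. Peak expression is the 99th percentile over the cell
type's cells pooled across both samples of the contrast — the symmetric
choice. Eligibility requires ≥ 30 cells in every sample.

Consensus intersects the replicate contrasts per (gene, cell type),
removes direction conflicts, and subtracts every batch-control hit.
Replicates are paired positionally (KO_r vs WT_r; equal replicate counts
required). The volcano collapse takes, per gene, the record with maximal
|LFC| — magnitude, not signed value, so strongly repressed genes are
represented — with ties broken by higher Bayes factor, then lexicographic
cell type. Direction bookkeeping: "up" = higher in KO = repressed by the
factor; "down" = induced by the factor.

## Composition and diversity

Fractions are per-sample proportions over all of that sample's cells.
The genotype log2 fold change averages, over test samples,
log2((f_sample + δ)/(f̄_ref + δ)) with the reference fraction the
arithmetic mean across reference samples (δ = 1e-6 guards empty types) —
the stable choice with unequal replicate counts. This convention is only
approximately antisymmetric under swapping reference and test (the mean
of logs is not the log of the mean); `per_pair=True` averages over all
sample pairs instead and is exactly antisymmetric. The flag rule is
|mean log2FC| > 0.5, strict. The expression threshold for "genes per
cell" (0.1) is read on the linear library-size-scaled scale, strictly;
the TRA fraction treats genes without a TRA call as non-TRA with a
warning and reports 0 for cells expressing nothing. Mean log expression
is the per-gene mean of ln(1 + linear normalized value) per genotype.

## Problem sizes and verification

The test suite and `scripts/acceptance.py` run everything at sizes where
the planted effects are comfortably identifiable on one CPU in seconds to
tens of seconds: a 20-type × 200-cell × 2,000-gene atlas for TRA recovery,
5,000 cells per genotype for density sign recovery, and 3 cell types ×
500 cells per group × 1,000 genes with 100 + 100 regulated and 50 batch
genes for consensus DE; filter cascades are cross-checked against
independent brute-force enumeration on 200 × 200 inputs over 50 seeds.
Passing these checks demonstrates correctness of the implementations
under the generators' assumptions (independent genes, clean cluster
geometry, known truth); it does not certify performance on real tissue
atlases, where intermediate restriction breadths, correlated programs and
embedding distortions blur every boundary quantified here.

## Known limitations

- Doublet scores are inputs (only the 0.2 threshold is owned here);
  ambient RNA, cell-cycle and batch-integration corrections are out of
  scope.
- The bootstrap Bayes factor saturates at ln(n_boot) ≈ 6.2 for
  n_boot = 500 and is a sign-stability measure, not a posterior odds from
  a generative model.
- The calibration model form is a package choice; other monotone E–τ
  links would give slightly different entropy thresholds.
- KDE bandwidths assume roughly Gaussian within-genotype geometry;
  heavily curved embeddings may need explicit bandwidths.
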