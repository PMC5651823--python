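# Methods

This note documents the statistical models, the defaults and the design
choices in `triadexpr`, and what the synthetic-data validation does and does
not establish.

## The triad design

Each tissue site contributes samples in three conditions: healthy tissue (H),
histologically normal tumor-adjacent tissue (A, "NAT") and tumor (T). Two
contrasts are primary — NAT vs healthy (A:H) and tumor vs NAT (T:A) — plus
tumor vs healthy (T:H) for the control-choice comparison. The central
objects are the nine expression models, the 3×3 combinations of {U, D, S}
status in A:H crossed with T:A. `UD` (up in NAT relative to both
neighbours) is tumor-adjacent-specific activation (TASA), `DU` its
repression counterpart, `UU`/`DD` gradients, `SS` the null.

## Normalization and unwanted variation

Genes with fewer than 10 reads in fewer than 2 samples are removed.
Upper-quartile CPM uses per-sample scale factors equal to the 75th
percentile (linear interpolation) of the sample's non-zero count *fractions*
(count/library size), rescaled to mean one. Computing the quartile on
fractions rather than raw counts makes the factors invariant to rescaling a
sample's counts by a constant, which is the defining property of the
normalization; effective library size is `libsize × factor`. The log2
transform uses pseudocount 1 on CPM.

Unwanted-variation factors are the first k left singular vectors of the
sample × control-gene log2-CPM matrix after centering each control gene.
The contract on the controls (housekeeping genes) is that they carry no
condition effect — they are *not* assumed free of technical variation, which
is precisely what makes them informative. k defaults to 1 and is bounded by
`min(#controls, #samples − 1)`. Two uses are distinguished deliberately:

* for testing, the factor scores enter the NB GLM as covariates, preserving
  the count-model likelihood;
* for scoring and diagnostics, each gene is regressed on the scores and the
  fitted part subtracted (intercepts kept, so gene means survive).

Normalization and factor estimation are performed within each tissue and
condition pair independently; pooling tissues would let the tissue baselines
dominate the control-gene variance and hide the technical factors.

RLE is `log2 expression − per-gene median across samples`; per-sample
medians near zero and small IQRs indicate successful normalization.

## Differential expression

Per gene g and sample j, counts are modelled NB with mean
`log μ_gj = x_jᵀ β_g + log(N_j s_j)` and variance `μ + φ_g μ²`, where x
holds an intercept, the group indicator and the optional factor covariates.
Significance is a likelihood-ratio test of the group coefficient against
χ²(1); the reported log2 fold change is the fitted coefficient divided by
ln 2 (no pseudocounts). All genes share the design matrix, so the IRLS
solver runs as batched weighted least squares across genes.

A gene is called U or D only if all three gates hold: Bonferroni-corrected
p < 0.05 (over the tested universe), |log2FC| > 1 (strict; "more than
two-fold"), and average log2 CPM > 3 (computed as `log2(mean CPM + 0.5)` on
UQ-CPM before factor removal). The abundance gate is evaluated before
factor removal because the removal step re-centers nothing and the gate is a
detectability criterion, not a biological one; both choices are exposed as
parameters.

### Dispersion

The per-gene dispersion is a method-of-moments estimate
`(var − mean)/mean²` on counts scaled to a common effective library size,
formed within each group, combined by residual degrees of freedom and
floored at zero, then shrunk toward the trimmed mean (20% total trim) of all
per-gene estimates.

The shrinkage strength is adaptive. Plug-in gene-wise dispersions make the
LRT anti-conservative in the far tail: a gene whose within-group variance is
by chance low receives both a small φ̂ and an inflated statistic, and at
Bonferroni-scale thresholds (p ~ 10⁻⁵) this dominates the family-wise error.
With the true dispersion supplied the tail is exactly calibrated, so the
defect is purely estimation noise. The estimator therefore gauges the
sampling noise of the gene-wise values from the disagreement between the two
per-group estimates, attributes only the excess between-gene spread to real
heterogeneity, and sets the shrinkage weight to `residual df × noise/signal`
(a standard random-effects weighting). On homogeneous-dispersion data this
collapses to the common value (and restores family-wise error control); on
heterogeneous data gene-wise estimates dominate. The configurable
`prior_df` (default 10) acts as a lower bound on the weight.

## Model enrichment and cross-tissue sharing

Within a tissue with G tested genes, the expected count of model XY under
independence of the contrasts is `G · p(X in A:H) · p(Y in T:A)` from the
marginal status rates; fold = observed/expected and p is the Poisson upper
tail at the expected count. `expected = 0` with positive observed is
reported as infinite fold and flagged.

For sharing across tissues, the per-gene probability of carrying a model in
≥ k of T tissues is the exact Poisson-Binomial tail over the per-tissue
marginal rates `q_t`, computed by O(T²) dynamic programming (validated
against 2^T enumeration). The expected shared count is λ = G·tail on the
*intersection* universe of genes tested in all tissues (the marginal rates
are computed on the same universe, keeping the null self-consistent), and
significance is P(Poisson(λ) ≥ observed). All Poisson p-values use the
upper-tail convention P(X ≥ observed).

Shared gene sets take genes with the model in ≥ `min_tissues` tissues
(default 3 for the TASA set). Directional consistency is the fraction of
genes whose log2FC sign agrees across all tissues, significance not
required.

## Gene-set scoring

**Single-sample enrichment (TASA score).** Genes are ranked by descending
abundance per sample (ties broken by stable gene order). With N genes and
position i, in-set genes carry weight `(N − i + 1)^α` (α = 0.25 by default);
the score is `Σ_i (P_in(i) − P_out(i))`, the integrated difference between
the weight-normalized cumulative in-set distribution and the uniform
cumulative over out-of-set genes. This is the sum statistic of the
single-sample lineage, not the maximum deviation; being rank-based it is
invariant to any strictly monotone per-sample transform. Across-sample
rescaling is available but off by default.

**Preranked enrichment.** ES is the maximum-deviation running sum with hit
increments `|score|^p / Σ_set |score|^p` (p = 1) and miss decrements
`1/(N − n_set)`. The null is gene-tag permutation: `n_perm` (default 1000,
seeded) random gene sets of equal size. Nominal p uses the same-sign null
with +1 correction (so p ≥ 1/(n_perm+1)); NES divides ES by the mean
same-sign null |ES|; FDR follows the standard positive/negative NES pooling
procedure, clipped to [0, 1].

**Score comparisons** use two-sided Mann–Whitney (exact when both groups are
≤25 and tie-free, asymptotic otherwise) with an explicit Bonferroni
correction factor and significance at corrected p < 0.001.

**Regulator ranking** pairs NAT and tumor samples by subject, computes
Spearman correlation of every tumor-side gene with the NAT-side TASA score
(rank-transform then vectorized Pearson; tied ranks averaged), drops
constant genes with a warning, and reports the descending table with
percentile ranks. At least 3 matched pairs are required.

## Deconvolution

With two references the simplex-constrained least-squares problem
`min ‖x − (1−f)h − f·t‖², f ∈ [0, 1]` has the closed-form solution
`f = clip(⟨x − h, t − h⟩ / ‖t − h‖², 0, 1)` — the exact quadratic program,
no iterative solver. References are the arithmetic mean healthy and tumor
profiles on the linear normalized-abundance scale (mixtures add linearly;
a log-scale option is deliberately not provided). Identical reference
columns are rejected as unidentifiable. No quantile pre-normalization is
applied by default.

## Control comparison

T:H and T:A DE tables are compared on the intersection universe: Pearson
correlation of log2FC over *all* tested genes (not only DEGs), DEG counts,
their overlap, mutual overlap fractions and the two discordance counts
(significant in both with opposite direction).

## The synthetic generator

Counts are NB(μ, φ) with
`log2 μ = baseline(tissue, gene) + condition effect + Σ_k score·loading +
log2 L_j`:

* per-(gene,tissue) baselines uniform on [3, 9] log2 (independent across
  tissues, giving well-separated tissue profiles);
* dispersion φ = 0.2 by default (typical for bulk tissue cohorts), scalar or
  per-gene range;
* two source cohorts with log-normal library-size factors, meanlog 0 vs 1.1
  (≈3-fold, emulating pronounced cross-cohort depth differences); healthy
  samples come from the first cohort, NAT/tumor from the second;
* one latent factor by default, standard-normal scores and N(0, 0.5²)
  loadings on *every* gene including housekeeping;
  `factor_condition_shift` optionally moves the scores with condition to
  create a confounded design;
* 50 housekeeping genes with zero condition effect in every tissue;
* per-tissue model assignment by the configured proportions (default ~12%
  of genes non-null), with symmetric log2-scale effects; the effect size
  defaults to the range [1, 3] (the magnitude distribution of real DEGs is
  not identifiable from published summaries, so it is config-exposed, and
  all recovery experiments pin it explicitly, typically to 2);
* `n_shared_tasa` genes planted UD in ≥ `min_shared_tissues` tissues and SS
  elsewhere; housekeeping, shared-TASA and driver genes are disjoint;
* NAT means of genes with no NAT-side plant (first letter S, not UD/DU) are
  convex mixtures `m·tumor + (1−m)·healthy` with per-sample m uniform on
  [0.05, 0.25] — modest tumor-cell admixture — so TASA plants are never
  diluted and truth labels stay unambiguous;
* in the matched design, each subject's standardized tumor driver level u
  shifts that subject's NAT-side TASA effects by `driver_effect · u` log2.

A single root seed feeds a global stream plus per-tissue substreams
(spawned deterministically), so identical configs give bitwise-identical
output and per-tissue regeneration is stable.

### What the validation shows — and does not

The validation scenarios (`triadexpr.validate`, run by
`scripts/acceptance.py` and the acceptance tests) measure, at desk scale:
exactness of the Poisson-Binomial tail (T ≤ 6); type-I error and family-wise
error of the DE test on null triads (2000 genes, 20/group, φ = 0.2, 20
seeds); recovery of planted |log2FC| = 2 effects at 30/group across 4
tissues (10 seeds, 1500 genes); null calibration of the model-enrichment
fold (100 replicates); deconvolution accuracy on noise-free and
NB-resampled mixtures (2000 genes); factor recovery and confounded-design
correction (20 seeds); scoring oracles and permutation-p calibration; the
NAT-specific TASA-score phenotype (success = both Mann–Whitney comparisons
Bonferroni-significant in ≥3 of 4 tissues, echoing enrichment "in most
tissue types"); driver recovery at 200 subjects (20 seeds) and rank
uniformity under a null driver (50 seeds); and tissue assignment (10
seeds). Problem sizes were chosen so the full battery runs in about a
minute while keeping Monte-Carlo error well inside the asserted margins.

The generator emulates the *statistical* structure the pipeline assumes; it
does not simulate read-level artifacts, GC/length biases, isoform switching,
correlated gene modules beyond the latent factors, outlier samples, or
cell-type composition. Passing these checks therefore demonstrates internal
correctness and calibration under the stated model, not performance on any
particular real cohort.

## Numerical choices and degenerate inputs

* IRLS: up to 100 iterations, convergence at max |Δβ| < 1e-10, linear
  predictor clipped to ±30, ridge 1e-10 on the normal equations; singular
  designs (factor collinear with group) are rejected with advice to reduce k.
* φ = 0 rows use the Poisson likelihood exactly rather than a large-r
  approximation.
* Tissue-assignment ties break to the first tissue in panel order and are
  logged; zero-variance profiles correlate as −∞ and never win.
* Constant genes in Spearman computations are reported NaN (co-expression)
  or dropped with a warning (regulator ranking); an empty gene set makes
  directional consistency NaN with a warning.
* All warnings (ties, dropped genes, skipped contrasts) go to the logger,
  never silently.

## Known limitations

* The NB test is a plain LRT; exact small-sample tests and quasi-likelihood
  F-tests are out of scope, so groups below ~5 samples are underpowered and
  mildly miscalibrated.
* Sharing statistics assume independence across tissues of the same gene's
  calls; subjects shared across tissues would violate this.
* Deconvolution is strictly two-reference; it measures tumor-likeness, not
  cell-type composition.
* The preranked FDR is the empirical pooling procedure and can be coarse
  for small collections at low n_perm.
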