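# Methods

## Overview

`cosig` asks which normal cell population a tumour transcriptome most
resembles. The chain is: replicated RNA-seq counts of sorted normal
populations → filtering and TMM normalization → precision-weighted genewise
linear models with empirical-Bayes variance moderation → per-population
signature genes with signed "next closest population" weights → weighted
signature scores of tumour profiles → weighted rotation gene-set tests of
signature–subtype association. Every stage is validated on synthetic data
with planted ground truth.

## Normalization and transforms

*Filtering.* A gene is kept if its CPM (computed on raw library sizes,
before normalization, since filtering precedes it in the workflow) strictly
exceeds `min_cpm` in at least `min_samples` samples. The defaults
(1 CPM / 3 samples) suit small replicated designs; for large cohorts a rule
like 0.1 CPM in ≥ 54 samples is expressed through the same two parameters.

*TMM.* The reference library is the one whose 75th-percentile CPM is
closest to the mean 75th percentile. For each sample, genewise log2 ratios
M and average log abundances A against the reference are formed over genes
nonzero in both; 30% of M and 5% of A are trimmed from each tail, and the
factor is 2 to the inverse-variance-weighted mean of the surviving M, with
delta-method weights (N−y)/(Ny) summed over the two libraries. Factors are
rescaled to multiply to 1. A sample sharing no expressed genes with the
reference gets factor 1 with a warning. The implementation reproduces
edgeR's `calcNormFactors(method="TMM")` to ten decimals on a frozen
fixture (tests/test_expression.py).

*log-CPM.* `log2((y + p_i) / (L_i + 2 p_i) · 1e6)` with effective library
size L_i (library size × TMM factor) and a library-proportional prior
count `p_i = prior_count · L_i / mean(L)`. The proportional prior maps a
zero count to the same log-CPM in every sample regardless of depth; the
default prior is 0.5 (configurable; 3 is conventional for heatmap
z-scores). RPKM divides CPM by gene length in kb and shares the prior
convention in its log2 variant.

*MDS.* The distance between two samples is the root-mean-square log2
difference over the k = min(top, G) genes with largest absolute difference
for that pair (default top = 500, the "leading" log fold change);
coordinates come from classical Torgerson scaling, eigenvalues sorted
descending with stable ties.

## Genewise models and moderation

*voom.* Genewise OLS on log-CPM; lowess (span 0.5, 3 robustness
iterations, via statsmodels) of the quarter-root residual variance against
average log2 count; per-observation precision weights are the trend value
at the fitted log-count, to the power −4, with flat extrapolation beyond
the data range. Weights agree with limma's voom to ~0.1% on a frozen
fixture; residual differences trace to lowess interpolation details.

*Moderation.* With genewise residual variances s², residual df d and
`e = log s² − ψ(d/2) + log(d/2)`, the prior df d₀ solves
`ψ'(d₀/2) = 2·(var(e) − ψ'(d/2))` by Newton inversion of the trigamma
function, and s₀² follows from mean(e). Posterior variances are
`(d₀ s₀² + d s²)/(d₀ + d)` with total df d₀ + d. If the spread of e does
not exceed its sampling expectation — or the fitted d₀ exceeds 10× the
residual df, a numerical-stability cap — d₀ is declared infinite and all
posterior variances equal s₀². Two degenerate-input rules: exactly equal
variances return that common value as the prior, and all-zero variances
are an error. The finite-d₀ branch matches limma's `squeezeVar` to eight
decimals on a frozen fixture.

*Tests.* TREAT with threshold δ = log2(τ):
`p = P(T ≥ (|β̂|−δ)/se) + P(T ≥ (|β̂|+δ)/se)` at df d₀+d; τ = 1 reduces
exactly to the two-sided moderated t. BH adjustment is the usual step-up
with cumulative-minimum enforcement; NaN p-values propagate and are
excluded from the test count.

## Signatures

At threshold τ a gene qualifies for population P if its BH-adjusted TREAT
p is below the FDR level in **all** P-vs-other contrasts and all oriented
fold changes share one sign. The working τ is the smallest grid value
(grid 1.00–1.20 in steps of 0.05) whose signature size is ≤ the size cap
(default 1,000); if none qualifies the largest grid value is used. The cap
and grid make explicit the practice of using larger thresholds for
populations with more signature genes. FDR is controlled within each
pairwise contrast separately, matching standard per-contrast TREAT usage.

The weight of gene g is the P-vs-other log2 FC of smallest magnitude —
"next closest" read per gene, the most conservative choice. A global
alternative (population nearest in expression space) was considered and
rejected because a single global neighbour under-weights genes whose
discriminating contrast is a different population; per-gene minima also
give the clean invariant |w_g| ≤ every pairwise |logFC|.

Cross-species transfer keeps only declared 1:1 orthologs, translates
identifiers and carries weights unchanged; 1:many and many:many pairs are
dropped and reported.

## Scoring and tumour association

Probe-level arrays are collapsed to genes by dropping probes at or below
the median average log expression or without a symbol, then keeping the
highest-average probe per gene. The tumour score is
`Σ w_g y_g / Σ |w_g|` over signature genes present in the matrix; missing
genes leave both sums (the only reading under which the score remains a
weighted mean). Scores are min–max scaled to [0, 1] per population;
constant scores map to 0.5 with a warning. Scores are affine-equivariant
in y, and scaled scores are invariant to affine transforms of raw scores.

The expression-quartile association splits tumours into rank quartiles
(stable ties by tumour identifier) and compares the proportion of genome
altered between Q1 and Q4 and adjacent pairs with pooled-variance t-tests
(Welch available via flag). The proportion itself is consumed as a
precomputed per-tumour scalar.

## Rotation gene-set tests

The design is reparameterized so the tested contrast is its last
coefficient; a full QR decomposition reduces each gene to a (d+1)-vector
v_g = (contrast effect, d residual effects), nuisance coefficients
projected out, orientation fixed so a positive effect means a positive
contrast. Observation weights, when present, are absorbed by
sqrt(weight)-scaling each gene's response and design (per-gene QR).

The observed statistic is T = Σ w_g z_g / Σ|w_g| with z the moderated t
mapped through Φ⁻¹∘F_t (evaluated through survival functions to keep tail
precision). Each of the B rotations draws one Gaussian vector of dimension
d+1, normalizes it, and applies it to **all** set genes — preserving
inter-gene correlation, the defining feature of rotation tests — giving
rotated effects r·v_g and rotated variances (‖v_g‖²−(r·v_g)²)/d, which are
re-moderated with the fixed d₀, s₀². p_up counts rotations with T ≥
observed, p_down ≤, each as (b+1)/(B+1), so p ∈ [1/(B+1), 1]; a mixed
p-value on the |z| statistic is provided for completeness but is not the
primary output. The set statistic is fixed to the weighted mean —
directional, matching the directional enrichment claims the test serves;
mean-squared and floor-mean variants are out of scope. The rotation stream
is a PCG64 generator seeded by the user's integer; identical seeds give
identical results.

Barcode data ranks genes by a contrast statistic (descending, stable) and
records positions of positive- and negative-weight signature genes plus a
"worm": triangular-kernel density of set positions divided by the uniform
expectation, boundary-corrected so 1 means no enrichment. Bandwidth
defaults to G/20 ranks — purely a plotting-data convention.

## Telomere qPCR

Standard curves are OLS fits of Cq on log2(input ng) over the four-point
dilution series (50, 16.7, 5.56, 1.85 ng); slope −1 per doubling is 100%
efficiency and non-negative slopes are rejected. Triplicate Cqs are
averaged on the Cq scale *before* curve inversion (the two orders differ
only at second order in the noise; pre-inversion averaging is the
conventional choice), with optional rejection of replicates > 0.5 cycles
from the median. T and S are the curve-inverted quantities; the T/S ratio
is reported relative to a reference sample, which maps to exactly 1.
Samples inverting more than 2 log2 units outside the curve range are
flagged, not dropped.

## Synthetic data

The generator emulates the shape of the real inputs, not their full
biology. Counts: per-gene baseline log2-CPM drawn N(5, 2²) (log-normal
abundances give the filtering rules realistic bite), converted to
proportions; sample library sizes uniform on 1.6–2.6 million reads for the
default 2,000 genes — per-gene depth equivalent to 16–26 M-read libraries
at a 20,000-gene transcriptome; negative binomial via Gamma–Poisson with
dispersion φ = 0.1 (var = μ + φμ², typical bulk biological variability).
Each population owns a disjoint planted signature (default 60 genes,
|log2 effect| = 3, random signs) applied multiplicatively in its own
samples. Defaults: 4 populations × 3 replicates, matching a three-patient
sorted-population design.

Tumours are generated directly on the log scale (microarray-like, matching
the scoring input): baseline + attenuation × origin effects + N(0, noise²),
default 50 tumours per origin subtype, attenuation 0.5, noise sd 1 —
tumours carry a diluted, noisy copy of their origin's signature. qPCR
plates emit standard-curve wells and triplicate sample wells from
configurable linear curves with Gaussian Cq noise.

All randomness flows from one integer seed through `SeedSequence.spawn`
with a fixed stream order (baselines, planted effects, library sizes,
counts, tumour noise, qPCR noise), so outputs are bit-reproducible and
enlarging one component does not perturb the streams of another.

What the simulation does *not* model: gene–gene correlation beyond the
planted block structure, composition effects, batch effects, tumour
purity, copy-number-driven expression, probe-level artefacts. Passing
tests therefore demonstrate correctness of the computations and
recoverability of planted structure under idealized noise — not
performance on real cohorts.

## Problem sizes and numerical choices

Tests run the default study (2,000 genes, 12 normal samples, 200 tumours)
once as a shared fixture; calibration suites use 400 null simulations with
B = 199 rotations and 100-gene matrices, sizes chosen to keep the whole
suite under a minute while leaving binomial noise on type-I estimates well
inside the asserted [0.02, 0.08] band. Headline rotation p-values use the
conventional B = 9,999. Other numerical conventions: trigamma inversion by
Newton iteration with closed-form seeds at the extremes; classical-MDS
eigenvalues clipped at zero before the square root; BH implemented with a
stable argsort so equal p-values keep input order; quartile ties broken by
tumour identifier order (the tie policy is a convention, stated here
because it affects which tumour lands in which quartile).

## Known limitations

- Voom weights differ from limma's in the third decimal because the lowess
  interpolation grids differ; all downstream conclusions are insensitive
  to this at the tested tolerances.
- The rotation test supports a single contrast per call; F-type multi-df
  set tests are not implemented.
- `moderate_variances` fits a constant prior; trended and robust priors
  are out of scope.
- Ortholog transfer is strict 1:1; no attempt is made to rescale weights
  across species.
- Proportion of genome altered must be supplied; deriving it from
  copy-number segments is out of scope.
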