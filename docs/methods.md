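# Methods

`mindnet` implements a complete case–control imaging-transcriptomics
analysis for cortical similarity networks, exercised end to end on
synthetic cohorts with known ground truth. This note records the models,
the estimator and parameter choices, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want to
know.

## MIND similarity networks

Each cortical region is represented by the cloud of its surface vertices in
the 5-dimensional space of morphometric features (cortical thickness CT,
gray matter volume GMV, mean curvature MC, surface area SA, sulcal depth
SD). Features are z-scored per subject across **all** vertices (population
sd), so scale differences between features cancel and a common affine
transform of the data leaves the network invariant.

The similarity between regions a and b is

    MIND(a, b) = 1 / (1 + D_sym),
    D_sym = (KL(a||b) + KL(b||a)) / 2,

which maps divergence 0 to similarity 1 and lies in (0, 1]. KL divergence
between the two vertex clouds is estimated non-parametrically with the
k-nearest-neighbour estimator of Wang, Kulkarni & Verdú (2009),

    KL(P||Q) ≈ (d/n) Σ_i log( ν_k(i) / ρ_k(i) ) + log( m/(n−1) ),

with ρ_k the k-th neighbour distance of x_i within its own sample
(excluding itself) and ν_k its k-th neighbour distance in the other
sample. Zero distances (duplicate points) are floored at 1e-12 before the
log; negative raw estimates are clipped to 0 so similarity never exceeds 1.

**Choice of k.** The matrix constructor defaults to an adaptive
k = max(3, round(n_min^0.4)) where n_min is the smallest region's vertex
count (k=5 at 50 vertices, k=12 at 500). Rationale: a network compares
hundreds of region pairs at once, so the *maximum* estimator error over
pairs is what matters; at k=1 the estimator's spread drives
identical-distribution pairs down to similarity ≈0.80 at 500
vertices/region, while the adaptive k keeps them above 0.9 without
noticeably biasing the Gaussian closed-form checks. The primitive
`knn_kl_divergence` keeps k=1 as its default; both accept any k.

A histogram-based Jensen–Shannon mode (`mode="js"`, similarity
1 − JS distance, base 2) is provided as an alternative divergence; the bin
count per dimension grows as (n/20)^(1/d), floored at 2, to keep joint
cells populated. It is coarser than the k-NN estimator and intended for
comparison, not as the default.

Regional MIND (weighted node degree) is the mean of a region's
off-diagonal similarities; global MIND is the mean of regional values. The
diagonal is NaN by convention and never enters degrees. Density
thresholding keeps the top ⌈density·E⌉ edges and zeroes the rest.

Implementation note: the full-matrix path computes one squared-distance
matrix and selects k-th neighbours with a compiled kernel; it is tested to
be numerically identical to composing `mind_similarity` per pair. Above
8000 vertices it switches to per-region KD-trees to bound memory.

## Synthetic cohorts

The generator is the source of ground truth for every downstream test.
Vertex features for subject j follow, per feature,

    x_v = μ[r(v)] + δ_r·group_j + site_offset + β_age·(age_j − 12)
          + β_tiv·z(TIV_j) + β_sex·sex_j + ε_v,   ε_v ~ N(0, noise_sd²),

with per-region baselines μ drawn once per geometry (sd 0.5) and the
standardized effect map δ applied to patients. With all effects zero the
model is exchangeable across groups and sites, which the null-calibration
tests rely on. Phenotypes carry age (U(8,16) years), sex (Bernoulli 0.5),
TIV (N(1500, 150) cm³), FSIQ and symptom scores with group-dependent
means, mirroring the covariates of a typical ADHD cohort table.

Geometry: each hemisphere owns its own full-sphere Fibonacci lattice of
centroids (the right hemisphere is the x-mirror of the left), the way
surface pipelines inflate each hemisphere to its own sphere; vertices are a
finer lattice assigned to the nearest centroid within hemisphere. The
default atlas has 308 regions (154 per hemisphere); the default test scale
is 60 regions × 50 vertices.

What the generator does **not** emulate: mesh topology, cortical folding,
feature cross-correlations, heteroscedastic vertex noise, or realistic
effect-size distributions (none are published for this design). Passing
tests therefore demonstrate statistical correctness of the pipeline under
a clean generative model, not performance on real MRI.

## Gene expression and gene sets

Expression is generated on left-hemisphere regions only (as in analyses
restricted to the better-sampled hemisphere). Non-signal genes are
independent Gaussian-process draws over region centroids with kernel
exp(−d/λ), d the great-circle distance; Cholesky factorization uses jitter
1e-8 (escalated to 1e-4 in the rare non-PD case). The default
λ = 2.0 rad makes the gene pool strongly dominated by a few smooth spatial
modes, emulating the dominant low-rank gradient of real cortical
expression; with rough (short-λ) genes the predictor block spans the
response and PLS1 "explains" most of any map, which is neither realistic
nor useful for testing.

Signal genes are a co-expressed module:

    g = α·z(target_map) + c·GP_shared + sqrt(1 − c²)·GP_gene,

with module coherence c = 0.7 by default. The shared component is what
lets PLS1 sit at a moderate response variance (≈0.2–0.4) while individual
signal genes remain detectable — with purely independent noise the module
average becomes almost noise-free and variance explained saturates.

Gene sets are uniform draws from the measured-gene universe, except one
designated set (and one stage×region grid cell) whose signal-gene content
is enrichment_ratio × the base rate. Sets are written and read as GMT.

## Site harmonization (ComBat)

Empirical-Bayes location/scale ComBat on regions × subjects matrices,
parametric (normal / inverse-gamma priors, iterative conditional updates,
tolerance 1e-6) and nonparametric (posterior over the other regions'
estimates, own region left out). Both modes reproduce Bioconductor
`sva::ComBat` on a fixed fixture to 1e-6 / machine precision; the frozen
reference lives in `tests/data/`. Biological covariates preserved by
default: group, age, sex, TIV. Harmonization is applied to regional MIND
values after network construction (the common practice for derived network
metrics); the routine itself works on any regions × subjects table.

Two intrinsic limits worth knowing. EB shrinkage deliberately leaves a
fraction of the per-region batch-mean *sampling noise* in place, so (i)
between-site SMD after harmonization approaches zero only as subjects per
site grow and as true site effects vary across regions (an informative
prior), and (ii) harmonization is only approximately idempotent — a second
pass moves values by a few percent of an sd, shrinking with n. The
nonparametric mode additionally cannot interpolate tail regions (its
posterior is supported on the other regions' estimates), so the parametric
mode is the right tool when near-complete removal is the goal; the
nonparametric mode remains the pipeline default for fidelity to common
practice.

## Propensity matching

Logistic regression of group on sex and age (statsmodels IRLS; ridge
fallback on perfect separation) yields probability-scale propensity
scores. Greedy 1:1 nearest-neighbour matching without replacement
processes patients in descending score order (ties by subject id) and
discards pairs beyond the caliper, 0.073 on the probability scale by
default. Balance is reported as standardized mean differences — pooled sd
= sqrt of the average of the two group variances (sample, ddof=1),
proportion-based for binary covariates — with |SMD| < 0.2 considered
acceptable. Zero pooled sd with unequal means returns +inf.

## Group contrasts

Per region, OLS of regional MIND on group (patient=1, so t > 0 ⇔ patient >
control) plus covariates age, sex, TIV and all their pairwise interactions
(group × covariate terms available behind a flag). Continuous covariates
are centred/scaled internally before products are formed, purely for
conditioning; the group t is unchanged. Bonferroni correction uses the
region count as family size; network-level analysis averages regions into
their (e.g. Yeo-7) networks at the subject level, reruns the same GLM and
corrects across networks. Clinical associations use partial Spearman
correlations (rank, residualize on covariates, Pearson on residuals, t
approximation) with Benjamini–Hochberg FDR across regions.

## Spin tests

Null maps are generated by uniform random 3-D rotations (sign-fixed QR of
a Gaussian matrix) applied to the left hemisphere's spherical projection,
with the x-mirrored rotation applied to the right hemisphere; each region
takes the value of the region whose rotated centroid lands nearest.
Non-bijective assignments are kept as-is, matching the cited rotation
procedure. The statistic map is the one spun; p-values use the add-one
convention p = (1 + #{null ≥ r_obs})/(n_perm + 1), one-sided on the
observed direction by default (two-sided on |r| available), so p is never
exactly zero. Defaults: 10,000 permutations, Spearman correlation.

## PLS and bootstrap gene statistics

The left-hemisphere t-map is the single response, per-gene z-scored
expression the predictors. Components come from NIPALS
(scikit-learn `PLSRegression`, no internal scaling); x-scores are
orthogonal, so the response variance explained by component c is
corr(score_c, y)² and the fractions sum to ≤ 1. Each component's sign is
fixed so its scores correlate non-negatively with the response. A
component is retained iff variance explained > 0.20 **and** its
spin p < 0.05, where the null refits the PLS on spun responses.

Gene stability: regions are resampled with replacement (10,000 bootstrap
replicates by default), the first component refit per replicate — for a
single response the first weight vector is the normalized covariance
direction X'y, so refits are exact and fast — and each replicate is
sign-aligned by correlating its region scores with the original scores on
the resampled regions. z = weight / bootstrap SE, two-sided normal p, BH
q; genes with q < 0.001 are split by weight sign into PLS1+ / PLS1−
ranked by |z|. Degenerate resamples (constant response) are redrawn and
counted. Bootstrap z for null genes is approximately standard normal
provided the component itself is well defined (signal present); with a
pure-noise response the sign-alignment step compresses the bootstrap
spread and inflates |z|, which is why the calibration test plants a
signal.

Single-gene analyses report Spearman correlations of each gene's map with
the t-map, BH-corrected across the supplied list; genes absent from the
expression matrix are flagged `measured=False` rather than dropped.

## Gene-set enrichment

Overlap tests draw size-matched candidate sets uniformly from the
measured-gene universe (the PLS sampling frame — not the genome), with the
exact hypergeometric tail computed alongside as a cross-check; the two
agree within Monte-Carlo error by construction. Rank enrichment is the
weighted Kolmogorov–Smirnov running sum (hit steps ∝ |z|, miss steps
uniform) with gene-label permutation. The developmental grid tests every
stage×region set with the exact hypergeometric and applies BH across all
grid cells (q < 0.05 flagged). BH families are never mixed across
collections. Gene identifiers are normalized (trimmed, uppercased) on
load.

## Pipeline and determinism

`run_pipeline` executes simulate → mind → harmonize → match → contrast →
spin → pls → enrich from one `PipelineConfig` (YAML round-trippable). The
master seed derives independent per-stage seeds by SeedSequence spawning,
and every output is a plain-text table, so identical configs reproduce
identical bytes; the manifest records per-stage timings and SHA-256 hashes
of all outputs. Reference-analysis defaults are preloaded: k adaptive,
10,000 spins, 10,000 bootstrap replicates, q < 0.001 gene threshold, >20%
variance retention, caliper 0.073, SMD < 0.2, Bonferroni α = 0.05.

## Problem sizes used in tests and the acceptance script

Unit and property tests run at 20–60 regions with 10–50 vertices per
region. The end-to-end checks use: 60 regions × 500 vertices for the
matrix contract; 9 cohorts of 100 subjects for GLM null calibration (540
region-tests); 20 replicate cohorts of 100 subjects for effect recovery;
100 regions / 200 spins / 500 tests for spin calibration; a 308-region
atlas with 500 genes (50 signal, strength calibrated to ≈30% PLS1
variance) for PLS recovery; 10,000-permutation enrichment on a 50-case
battery; and 1000 subjects/site for harmonization effectiveness, where the
SMD bound is binding. `scripts/acceptance.py` runs the orchestrated
pipeline at 100 regions, 40+40 subjects, 1000 spins and 2000 bootstrap
replicates. These sizes were chosen as the smallest that make each
statistical property measurable with comfortable margins.

## Known limitations

- The divergence estimator is biased upward for heavy-tailed or strongly
  clustered vertex distributions; similarities are comparative, not
  absolute densities.
- Spin tests assume region values live on (each hemisphere's) sphere with
  approximately isotropic autocorrelation; strongly anisotropic maps can
  remain miscalibrated.
- EB ComBat limits described above; longitudinal and GAM-based variants
  are out of scope.
- The synthetic generator's realism limits are listed in its section; in
  particular, effect sizes are chosen for statistical power, not clinical
  fidelity.
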