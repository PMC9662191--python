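# Methods

`omicspanel` implements a multi-omics biomarker-discovery workflow for
matched case–control cohorts: per-layer feature selection by combined
LASSO / elastic-net stability selection, logistic panel modeling with
honest AUC characterization, a beta-binomial differential test for
spectral counts, alpha/beta diversity summaries, and a cross-omics
correlation network. A synthetic cohort generator with planted effects and
latent factors supplies ground truth for every stage.

## The discovery model

Each two-group comparison (e.g. CRC vs. control) operates on one or more
feature tables (samples × features). Tables are auto-scaled — every
feature mean-centered and divided by its sample SD (n−1 denominator) — so
penalized coefficients are comparable across features and layers.

**Penalized logistic models.** For a binary outcome y and standardized
matrix X, the solver minimizes

    (1/n) Σᵢ log(1 + exp(−ηᵢ(2yᵢ−1))) + λ·[α‖β‖₁ + (1−α)/2·‖β‖₂²],

with an unpenalized intercept; α = 1 is the LASSO, α = 0.5 the elastic
net default. The solver is an iteratively-reweighted-least-squares
coordinate-descent path algorithm (the standard sparse-GLM decomposition),
numba-compiled, warm-started down a descending λ grid with an active-set
inner loop. Probabilities are clipped at 1e−5, the convergence tolerance
is 1e−8 on the weighted quadratic parameter change, and zeros are exact:
a feature enters only when the soft-threshold condition is violated. At
β = 0 the null solution is stationary iff max |xⱼ′(y−ȳ)|/n ≤ λα, which
defines λ_max; the grid holds 50 log-spaced points from λ_max down to
0.001·λ_max, expressed as fractions of λ_max so the range is scale-free.
(An interval of penalties "from 0 to 1" is only meaningful after this
normalization.) Tests cross-check the solver against scikit-learn's saga
solver and an independent likelihood-maximization oracle.

**Penalty tuning.** λ is chosen by stratified 10-fold cross-validation
maximizing mean held-out AUC, ties broken toward the larger λ (sparser
model). A `one_se` rule is available: the largest λ whose mean AUC lies
within one standard error of the best. The default follows the plain
arg-max contract; note that with ~6 validation samples per fold the fold
AUC is very coarse, so on pure-noise data the arg-max rule frequently
lands on non-sparse models — an inherent property of AUC-based tuning at
this sample size, not a solver artifact. The one-SE rule is systematically
sparser and is the recommended choice when false selections are costly.

**Stability selection.** The selection loop repeats (default 100
iterations): draw a stratified 75% training subset (a stratified-bootstrap
mode exists), tune λ by CV for LASSO and for the elastic net separately,
fit both at their tuned penalties, and record the nonzero supports. The
per-feature combined frequency is the sum of the two methods' selection
counts (range 0..200 at the defaults). Features are ranked by combined
frequency, and the **first quartile** of the ever-selected features —
those at or above the 75th percentile of the positive frequencies,
boundary ties included — becomes the layer's marker set.

**Second-stage cross-omics panel.** The per-layer marker sets are pooled
into one standardized matrix and the identical selection procedure runs
again; the surviving first quartile is the combined panel. This is the
step that compresses, say, thirty per-layer markers into a small
cross-omics panel.

**Honest evaluation.** Before any selection, the pipeline holds out a
stratified 25% of samples. All stability selection (per-layer and second
stage) sees only the remaining 75%; the reported test AUC fits the panel
on those training samples and scores the untouched 25%. Without this,
feature selection over the full cohort inflates a post-hoc "test" split
AUC to ≈0.85 even on pure noise at n = 60 with 200 features. The apparent
(full-data, resubstitution) AUC is also reported and labeled, since many
published panel AUCs are of that kind. Panels are additionally
characterized by:

* a **bootstrap AUC distribution** — stratified within-class resamples,
  panel refit, AUC on the out-of-bag samples (avoids resubstitution
  optimism);
* a **random-label null** — labels permuted each iteration, panel refit on
  a stratified 75% of the permuted data, AUC on the held-out 25%; its mean
  sits near 0.5 and locates chance performance;
* **sensitivity/specificity** at the threshold maximizing Youden's J
  (ties resolved toward higher specificity), computed from the full-data
  fit's scores.

A fixed reference panel — by default the hemoglobin subunits HBA1, HBB,
HBD.HBE1 and HBG2.HBG1, the stand-in for fecal immunochemical testing —
runs through the same evaluation path for comparison.

**Differential testing.** The beta-binomial test models a protein's
spectral count kᵢ given the sample total nᵢ as BetaBin(nᵢ, π, ρ) with
overdispersion ρ = 1/(a+b+1); ρ → 0 recovers the binomial. The null
shares one π across groups, the alternative gives each group its own π
with ρ shared; ρ is profiled out by bounded one-dimensional optimization
(tolerance 1e−8) with the ρ = 0 boundary evaluated explicitly, and π
maximized per group within the profile. Twice the log-likelihood ratio is
referred to χ²(1). All counts zero in both groups returns p = 1 with a
degeneracy flag. Fold changes are ratios of group means with a
pseudocount (default 1 for counts, 0 for concentrations), flagged at ≥2
or ≤0.5. No multiple-testing correction is applied by default, matching
how raw significance counts are usually reported; Benjamini–Hochberg can
be applied downstream.

**Diversity.** Alpha diversity is Shannon entropy in nats; beta diversity
is Bray–Curtis on relative abundances with a PERMANOVA pseudo-F
permutation test (999 permutations, +1-smoothed p-value, explicit
generator for reproducibility). These are the field-standard defaults;
the metric choice is configurable.

**Network integration.** Selected features from all layers (pooled over
both comparison groups, autoscaled values) are correlated pairwise —
Pearson by default, Spearman and Kendall for cross-method consistency.
Edges keep unordered pairs with |r| ≥ 0.3 (inclusive) and p < .05
(strict); both boundary conventions are fixed so edge sets are
bit-reproducible. Isolated selected features remain as nodes. No
correction for multiple edge tests is applied, mirroring common practice
in published integration networks; treat edge counts descriptively.
Compositional effects on taxon correlations are not modeled (no
SparCC-style adjustment) — a known limitation.

## The synthetic cohort generator

The generator emulates a fecal multi-omics case–control study with groups
CRC (12), adenoma (21) and control (20) — sizes configurable — and three
layers measured on the same samples:

* **Microbiota** (225 taxa): per-sample depth log-normal with median
  23,041 reads (σ = 0.35); compositions Dirichlet-multinomial around a
  heavy-tailed (log-normal, σ = 2) baseline with Dirichlet concentration
  p/θ (θ = 0.02 by default; θ = 0 is pure multinomial). Planted group
  effects multiply the baseline **before** renormalization, so induced
  effects are compositional, not absolute. Zero-depth draws are redrawn;
  no all-zero sample is emitted.
* **Proteome** (521 proteins): spectral counts, per-feature beta-binomial
  given a log-normal sample total (median 3,000 spectra, σ = 0.35) with
  overdispersion ρ = 0.01 and log-normal (σ = 1.3) baseline proportions.
  These three values were fixed once so a typical sample detects ~169 of
  the 521 proteins (range ≈ 120–220), the scale of real fecal LC-MS/MS
  runs; matching the test's assumed model makes the type-I calibration
  check meaningful.
* **Amino acids** (44): log-normal concentrations (σ = 0.5 on the log
  scale) with a missing-at-random quantification mask whose per-feature
  detection probabilities (Beta(3,2)) yield ~26 quantified compounds per
  sample; missing values are encoded as 0, the same convention the reader
  applies to input data.

Planted signals are log-fold changes (count layers) or standardized
log-scale shifts (concentrations) applied to one feature for one group of
a contrast; effect 0 leaves the feature exchangeable, which the test
suite verifies by type-I calibration of downstream tests.

**Latent factors** induce known cross-layer correlations: a standard
normal factor (variance V) is added to each loaded feature's stored
values scaled by its loading (counts rounded and clipped at 0). For two
loaded features with loadings l_a, l_b and pre-injection empirical SDs
s_a, s_b the expected Pearson correlation is

    r = l_a l_b V / sqrt((l_a² V + s_a²)(l_b² V + s_b²)),

recorded in the ground truth. Injection is additive on the stored value
scale for all layers (rather than a log scale) because downstream
correlation runs on autoscaled — i.e. affinely transformed — values, so
the closed form above stays exact through the analysis. The rounding and
clipping of counts bias r slightly for low-abundance features; choose
loadings against abundant features when exact recovery matters.

Covariates (age, sex, BMI, smoking) are drawn from common distributions
across groups, mimicking a matched design; downstream models use features
only. A single root seed spawns named substreams per layer, so layers are
independently regenerable and identical designs are bit-identical.

**What the generator does not emulate:** batch effects, sequencing-run
structure, taxon phylogeny, protein–protein abundance coupling beyond the
latent factors, non-log-normal concentration shapes, informative
missingness, or longitudinal sampling. Passing tests therefore show that
the machinery is correct and calibrated under the stated models, not that
the pipeline's selections on real fecal data would match any particular
published marker list.

## Numerical choices and degenerate inputs

* Sample SD uses the n−1 denominator everywhere.
* Zero-variance features are dropped (with a warning) by autoscaling and
  by the correlation stage, never imputed.
* Ties: AUC gives half credit (Mann–Whitney); first-quartile boundary
  ties are all included; CV λ ties go to the larger λ; Youden ties go to
  the higher-specificity threshold; ranking ties break by feature ID.
* Perfectly separated logistic fits fall back to a tiny ridge (λ = 1e−6)
  and are flagged.
* Iterations that draw a single-class training set or out-of-bag set are
  redrawn and logged.
* CV folds reduce (with a warning) when the minority class cannot fill
  10 folds — routine at n ≈ 30 per comparison.

## Problem sizes in the shipped checks

The test suite and the acceptance script run entirely on generated data:
the stability-selection benchmark uses 2×30 samples with 200 features and
5 planted effects of 1.5 SD (100 iterations × 2 methods, 10 seeds); the
end-to-end runs use the full default cohort (53 samples; 225/521/44
features) at 100 iterations; calibration checks use 500 simulated
proteins and ≥2,000 correlation pairs. A complete default-cohort
comparison takes on the order of a minute on one core; the numba solver
compiles once per environment (a few seconds) and is cached thereafter.

## Known limitations

* The selection machinery is logistic-model based; no tree ensembles or
  nonlinear learners.
* Edge p-values and per-feature tests are reported uncorrected by
  default.
* Taxon correlations ignore compositionality.
* The λ grid's lower bound (0.001·λ_max) can truncate extremely dense
  solutions; raise the grid resolution for p ≫ 10³.
* With ~8 test samples in a 32-sample comparison, single-split test AUCs
  are coarse (granularity ≈ 0.03); the bootstrap distribution is the more
  stable summary at this scale.
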