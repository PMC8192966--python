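# Methods

## Scope and model

The package measures the reliability of local surrogate explanations of
brain-age regressors on multi-site morphometric data. The pipeline is:
simulate (or load) a subjects × features cohort; train feed-forward age
regressors under resampled leave-one-site-out cross-validation; attribute
each held-out subject's predictions with two local surrogate methods;
quantify within-subject stability and between-subject structure of the
attributions; compare the two methods' age-related feature sets.

## Cohort simulator

The simulator emulates the features of multi-site structural-MRI cohorts
that matter for this analysis, and nothing else:

- **Sites** with individual sample sizes and age ranges. Ages are drawn as
  site minimum + a log-normal offset (median = range/4, σ = 0.6), clipped to
  the site maximum: the overall distribution is right-skewed with a sparse
  old tail, the regime in which LOSO generalisation degrades.
- **Planted age effects.** Feature p of subject i is
  `slope_p·age_i + q_p·(age_i − mean age)² + offset[site,p] + ε`. A
  configurable subset of features carries nonzero slopes (default 10 of 60,
  slopes ±0.6…±1.5 feature-units/year); a `nonlinear_fraction` (default
  0.2) of those also gets a mild quadratic term (25% of the linear span at
  the age extremes). All other features are batch offset plus noise.
- **Batch effects.** Additive per-site, per-feature offsets
  `N(0, site_offset_sd²)` (default 0.5) and multiplicative factors
  `exp(N(0, site_scale_sd²))` (default 0.05).
- **Covariates.** FIQ ~ N(112.1, 11.7²), representable as missing for whole
  sites; SNR ~ N(site mean, 2.5²) truncated at 1. Feature noise is scaled by
  `(mean site SNR / SNR_i)^c` with coupling c = 0.5 by default, so
  low-quality scans are noisier.
- The full-scale preset (`abide_like_config`) uses 17 sites totalling 378
  subjects with the published per-site sizes, age ranges and SNR means, two
  sites with missing FIQ, and P = 1,213 features.

What it does **not** emulate: spatial covariance between regional
descriptors, realistic feature units/scales per descriptor family,
non-Gaussian measurement error, or site-by-age interactions. Passing tests
therefore demonstrate that the *measurement chain* behaves correctly on
data with known structure, not that any conclusion transfers to a specific
real cohort.

## Age regressor

A fully connected network with a single linear output unit, implemented in
numpy for bit-reproducible single-threaded training. Default configuration:
4 hidden layers × 512 ReLU units, Huber loss (δ = 1), SGD with learning
rate 5e-5 and momentum 0.9, dropout 0, early stopping (patience 20)
monitored on an internal validation split (default 10% of the training
subsample, redrawn per round), features z-scored with parameters fitted on
training subjects only. Desk-scale studies use `small_model_config` — 2×32
units, Adam 1e-2, squared loss, ~120 epochs — which trains in ~50 ms per
round on the default simulated cohort; the test fixtures use a 1×8 variant
because larger nets memorise 30-row training sets and stop generalising.

Per-(fold, round) seeds are `base_seed + fold·10⁴ + round`, so any single
model is reproducible in isolation. Overall MAE/R are computed on
per-subject predictions averaged over the N rounds; per-round overall
metrics are also retained. Per-site R on one- or two-subject sites is
reported as the NaN sentinel rather than a number.

The permutation test re-runs the full cross-validated fit with shuffled
ages; `p_MAE` is the fraction of permutations with MAE ≤ observed and `p_R`
the fraction with R ≥ observed (better-than-observed under the null). No
(b+1)/(m+1) smoothing by default — a zero is reportable — with the smoothed
estimator available via a flag. The trainer is injectable, so the same
machinery runs with a constant (training-mean) predictor for null
calibration.

## Surrogate explainers

Both methods minimise a proximity-weighted squared loss between the
black-box f and a linear surrogate g over a neighbourhood of simplified
inputs, plus a complexity penalty; they differ in neighbourhood, kernel and
penalty.

**Shapley kernel.** Coalitions z ∈ {0,1}^P; absent features are replaced by
background rows (default 100 rows sampled from the round's training
subsample — never the explained subject's site); weights
π(s) = (P−1)/(C(P,s)·s·(P−s)); empty/full coalitions enter as the
local-accuracy constraint base + Σφ = f(x), eliminated analytically before
the weighted least-squares solve. With all 2^P − 2 proper coalitions
enumerated the solution equals the exact Shapley values of the induced game
v(S) = E_bg[f(x_S, b_{−S})]; an independent full-enumeration oracle
(`exact_shapley`, P ≤ 14) verifies this to 1e-6 in the tests. When
enumeration exceeds the budget, complete coalition-size levels are taken
from the extremes (1, P−1, 2, P−2, …) inward, and the remaining budget is
filled with paired draws (coalition + complement) — a variance-reduction
choice. Degenerate solves (constant predictor) fall back to φ = 0 with a
flag.

**LIME surrogate.** Perturbations x + ε·sd with ε ~ N(0,1) and sd the
per-feature training standard deviations (zero-variance features held
fixed, coefficient 0); weights exp(−‖ε‖²/w²) with default width
w = 0.75·√P in standardised space; weighted ridge fit (λ = 1 by default)
with optional top-k pre-screen by absolute weighted covariance. Continuous
features are perturbed without discretisation. Coefficients are returned in
raw feature units (standardised-space fit divided by sd), so a linear
predictor's weight vector is recovered exactly in expectation; for smooth
predictors the coefficients approach the local gradient as the width
shrinks. Defaults: 2P + 2048 coalitions (Shapley) and 5,000 perturbations
(LIME); the desk-scale preset uses 256 coalitions over a 25-row background
and 1,000 perturbations, the smallest budgets that keep the surrogate fit
well-conditioned at P = 60 while the full study runs in minutes.

Explainer randomness is seeded from (fold, subject, training-subsample
content), so identical models trained on identical subsamples produce
identical stack rows while distinct rounds stay decorrelated.

## Reliability and comparison statistics

- **Intra-consistency (IC):** Pearson correlation between every pair of a
  subject's N attribution vectors (N(N−1)/2 values); zero-variance rows
  yield sentinel pairs excluded from the mean with a logged count. IC can
  be negative and is reported as such.
- **Inter-similarity (IS):** T × T correlation matrix of resampling-averaged
  vectors, symmetrised, unit diagonal, NaN sentinel for zero-variance
  subjects (excluded from clustering with a logged list).
- **Clustering:** partitioning-around-medoids on d = 1 − IS (negative
  similarities allowed; range [0,2], no clipping), 20 seeded restarts per
  k, k chosen by maximum mean silhouette over k ∈ [2,15] by default. An
  all-equal dissimilarity matrix is rejected as non-clusterable.
- **Cluster covariate tests:** Kruskal–Wallis omnibus per covariate
  (age/FIQ/SNR), Bonferroni-multiplied by the number of testable
  covariates; when significant, all-pairs Tukey–Kramer on the raw values
  (the classical pairing, kept deliberately), with a rank-based Dunn
  alternative behind `posthoc="dunn"` for users uncomfortable with the
  parametric post-hoc after a nonparametric omnibus.
- **Comparison:** per-subject correlation between the two methods' averaged
  vectors; per-feature attribution-age correlation with two-sided p values
  multiplied by P (capped at 1); tail sets via linear-interpolation
  percentiles of the defined r values, membership by ≥/≤ so ties at the cut
  enter; the symmetric threshold grid (75/25 … 99/1, step 2, 13 pairs);
  Jaccard with J(∅,∅) defined as 0 plus a flag; permutation significance by
  independently permuting each method's r vector over feature labels. A
  rank-sum + Cohen's d utility contrasts the two r distributions.

## Numerical and design choices

- Undefined correlations (zero-variance input) are NaN sentinels, never
  silently 0; they propagate to reports as explicit nulls.
- Weighted least squares uses `lstsq` (minimum-norm under rank deficiency);
  non-finite solutions trigger the zero-attribution fallback flag.
- The desk-scale study (6 sites, T = 300, P = 60, N = 20 rounds) is the
  default test bed; it exercises every stage in ~2 minutes on one CPU.
  Calibration suites run at reduced replication (50–200 replicates,
  100–200 permutations) with fixed seeds.
- Tail-set recovery of the planted features has a structural ceiling worth
  knowing: a planted feature's attribution grows with age regardless of the
  sign of its slope, so attribution-age correlations of planted features
  are positive and only the upper percentile tail can recover them; and at
  the 97/3 thresholds the tail set holds exactly 4 of 60 features, so its
  Jaccard against a 10-feature planted set cannot exceed 0.4 (observed
  ≈ 0.17). Rank-based recovery (planted features occupying the top |r|
  ranks) is the informative check at this scale and is what the desk study
  demonstrates (10/10 in the top ten ranks).

## Known limitations

- The sampled-coalition Shapley estimator is exact only under full
  enumeration; its sampled-regime error is checked loosely (rank
  agreement), not bounded.
- The reference SHAP/LIME packages' additional machinery (discretised LIME
  variants, model-specific Shapley algorithms, gradient explainers) is out
  of scope.
- Training determinism holds for single-threaded numpy; BLAS-threaded runs
  may differ in the last bits.
- The simulator's independence of features given age understates the
  attribution ambiguity correlated descriptors create in real morphometry;
  IC values on real data should be expected to be lower at equal model
  quality.
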