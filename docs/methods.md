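# Methods

`clpntraj` analyses three-wave panels of the GAD-7 (7 anxiety items) and
PHQ-9 (9 depression items), both scored 0–3 per item. The pipeline has
four stages: descriptive comorbidity statistics, parallel-process growth
modelling on wave-level mean scores, cross-lagged panel network (CLPN)
estimation on binarized symptoms, and resampling-based accuracy,
stability and replicability analysis. A synthetic-data module generates
panels with known ground truth so that every stage is testable without
access to any cohort.

## Scoring and descriptives

Scale sums (GAD 0–21, PHQ 0–27) are flagged clinical at a cutoff of
`sum >= 7`, the screening convention for both instruments; mean item
scores (0–3) put the two scales on a common metric for growth modelling.
Item presence for the network stage is `score >= 1`.

Prevalence trends across waves are tested with a Pearson chi-square on the
waves × {flagged, not} table, treating waves as independent samples (the
repeated cross-sectional reading; a paired McNemar-type test is a
non-goal). The accompanying effect size is the contingency coefficient
`eta = sqrt(chi2 / N_total)` with `N_total = waves * n`; this is the
definition that is consistent with both published example values the test
suite checks, and it is reported as such. Comorbidity rates are
`P(anxious at wave s | depressed at wave t)` for `s >= t`.

## Parallel-process growth models

Each subject contributes a 6-vector `y = (A1, A2, A3, D1, D2, D3)` of mean
scores. Time scores are fixed at 0, 1, 2 — equal spacing is assumed
because only a linear form is identified with three waves and no
calendar-time scores are part of the design.

**PP-LGCM** (single population): `y ~ MVN(Λμ, ΛΨΛ' + Θ)` with four growth
factors (intercept and slope per process), free 4×4 covariance Ψ and
diagonal Θ (six free residual variances). Ψ is parameterized by its
Cholesky factor (PSD by construction), residual variances by their logs
(bounded in [e^-18, e^6]); the mean vector is profiled out by GLS inside
the objective, which is minimized with L-BFGS-B from least-squares
starting values plus up to two perturbed restarts. Fit indices derive from
the LR statistic `T = 2(ll_saturated − ll_model)` (df = 7) against an
independence baseline (free means, diagonal covariance, df = 15):
`RMSEA = sqrt(max(T − df, 0) / (df (n − 1)))`,
`CFI = 1 − max(T − df, 0) / max(T0 − df0, T − df, 0)`, TLI analogous and
clipped at 1. The intercept–intercept and slope–slope correlations from Ψ
quantify co-development. A near-singular sample covariance (noiseless
input) receives a 1e-10 jitter with a warning.

**LCGA** (class enumeration): a K-component mixture with class-specific
growth-factor means, zero within-class growth-factor variance, and
residual variances shared across classes but free per process (two
parameters). The sharing choice is for parsimony and EM stability; the
per-process freedom respects the different item counts of the scales.
Fitting is EM; the observed-data log-likelihood is non-decreasing by
construction and asserted in tests. Parameter count is
`q = 4K + 2 + (K − 1)`, with `AIC = −2ll + 2q`, `BIC = −2ll + q ln n`,
`aBIC = −2ll + q ln((n + 2)/24)` and relative entropy
`E_K = 1 + Σ p_ik ln p_ik / (n ln K)`.

Initialisation: per-subject least-squares (intercept, slope) features per
process → k-means with K clusters, plus random-subject restarts; when
classes are enumerated incrementally the (K−1)-class solution also
contributes K−1 "split one class along the intercept axis" starts. The
split starts matter: a 3% high-severity class nested inside a broader
class is routinely missed by k-means starts alone, which makes the
information criteria prefer larger K for the wrong reason. Convergence is
a relative log-likelihood change below 1e-7 (500 iterations cap);
restarts that empty a class (soft count < 1) are discarded, and classes
are canonicalized by ascending `alpha_A + alpha_D` to remove label
switching. K = 1 is fitted in closed form (OLS growth means, pooled
residual variances) and doubles as the EM oracle in tests.

**BLRT**: the K−1 vs K test simulates `reps` datasets from the fitted
(K−1) model, refits both on each, and reports
`p = (1 + #{LR_b >= LR_obs}) / (reps + 1)` with LR values clamped at 0.
The Monte-Carlo p-value is valid for any statistic computed identically on
observed and simulated data, so the desk-scale settings (one or two EM
starts, tolerance 1e-5) trade a slightly noisier LR for a large speed-up
without biasing the level; the suite verifies the empirical rejection rate
at the nominal 5% over 200 repetitions. The LMR-LRT approximation is
deliberately not implemented; BLRT is the enumeration test.

## Cross-lagged panel networks

For each of the 16 symptoms at wave t+1, an L1-penalized logistic
regression on all 16 presences at wave t plus optional baseline
covariates. The coefficient matrix is oriented [predictor, outcome];
`exp(B)` gives the odds-ratio view (OR = 1 ⇔ no lagged association). An
"estimated edge" is any coefficient that survives the penalty — nonzero
at machine precision, with no post-hoc threshold.

Choices the CLPN literature leaves open, with the defaults taken here:

- Penalty: lasso, per-outcome λ by stratified 10-fold cross-validated
  deviance, fold split seeded. Rule `"min"` (default — it reproduces the
  dense networks typical of large cohorts) or `"1se"` (sparsity-oriented;
  used in the support-recovery and null-sparsity tests, where the flat CV
  curve makes `"min"` keep a several-percent fringe of noise edges).
- Symptom predictors enter raw as 0/1 (common scale, no standardization);
  covariates are standardized to unit variance and left effectively
  unpenalized. liblinear has no per-feature penalty weights, so the
  penalty-factor device is used: covariate columns are pre-scaled by 1e3,
  shrinking their penalty by the same factor, and coefficients are scaled
  back (reported per covariate SD). Intercepts are unpenalized the same
  way via liblinear's intercept scaling.
- The λ path is `λ_max` down to `max(1e-3 λ_max, 1e-4)` (30 points,
  geometric), where `λ_max = max |X'(y − ȳ)|/n` over symptom columns. The
  absolute floor stops near-constant outcomes from requesting an
  effectively unpenalized — and very expensive — end of the path. Path
  descent stops early once the CV curve has passed its minimum by one
  standard error with five grid points of patience. Outcomes with fewer
  minority cases than folds skip CV and take λ_max; constant outcomes
  yield an all-zero column with a warning. Networks are refused below
  n = 50.
- Expected influence: out-EI of node i is the row sum of B over j ≠ i,
  in-EI the column sum over i ≠ j — the autoregressive diagonal is
  excluded (standard practice when "connections" means between-symptom
  edges), and sums are on the log-odds scale. Both choices are switchable
  (`include_autoregressive`). Standardized EI columns are z-scores across
  the 16 nodes (sample sd); a node is "influential" when standardized
  out-EI > 1.

## Bootstrap accuracy and case-dropping stability

Edge accuracy: nonparametric subject bootstrap (default B = 1000;
desk-scale runs use 250), 95% percentile intervals per edge; edge or
centrality differences are significant when the bootstrap interval of the
difference excludes 0 (no multiplicity correction, mirroring the
referenced methodology). Bootstrap refits reuse the full-sample λ per
outcome by default — re-running CV in every replicate multiplies runtime
by the path length and changes point estimates only marginally; a
`reselect_lambda` switch restores the full procedure. Replicates with a
constant outcome record a zero column.

Stability: for each drop proportion p in 0.05..0.75 (step 0.05),
`B_per_prop` subsamples (default 250) of size `ceil((1−p) n)` without
replacement; the subsample raw EI vector is correlated with the
full-sample one. Raw (unstandardized) EI is used because standardizing
within subsamples would mask scale shrinkage. The CS coefficient is the
largest p such that for every proportion up to p the 5th percentile of
correlations is >= 0.7 ("with 95% certainty"), scanned monotonically and
stopped at the first failure; an undefined correlation (constant EI
vector, as happens for near-empty null networks) counts as a failure.
Proportions leaving fewer than 50 subjects are skipped.

## Replicability of two lagged networks

Networks for consecutive wave pairs are compared on the OR scale (the
scale on which edge summaries are reported; a log-OR option exists). An
edge is "present" when its coefficient survived the penalty. Support
conventions — the point the comparison literature leaves ambiguous — are:
union of supports for the "all" and "cross-lagged" correlations (an edge
absent in one network enters at OR = 1), all 16 diagonal entries for the
autoregressive correlation, intersection for the "replicated" subset.
Counts and mean ± sd are per network over that network's present edges,
percentages relative to its total edge count; % replicated is
`|intersection| / |support|` per network. Subsets with fewer than 3
entries report an undefined correlation. Centrality correlations are
Pearson r (with p) over the 16 raw in-EI and out-EI values.

## Synthetic data

The growth-mixture generator draws class k with probability π_k, builds
the latent mean score `α_k + β_k t + u_i + v_i t` (within-class sds
default 0 — pure latent-class growth; a cross-process correlation for the
deviations is available), clips to [0, 3], and emits each item as
`round(clip(Normal(mean + item_offset, item_sd), 0, 3))`. The discretized
clipped normal is deliberately simpler than a graded-response IRT model:
the analyses consume only sums/means and binary presence, so matching the
first two moments of item scores suffices. Two consequences are worth
knowing: near the scale boundaries clipping biases the observed mean away
from the configured line (recovery tests therefore place class lines in
the interior), and a latent wave mean at a half-integer cannot be realized
exactly by integer item scores. Default conditions mirror the targeted
three-wave design: class proportions (0.698, 0.272, 0.030) — a large
low-symptom class, a growing middle class, a small chronic class — item
dispersion 0.55, and baseline covariates (sex ~ Bernoulli(0.5), age
uniform on 17–24, four pandemic-exposure indicators) with no effect on
outcomes unless configured. One master seed spawns per-stage child
generators, so output is bit-identical for a fixed seed.

The network generator draws wave 1 from configured prevalences and each
later wave symptom-wise from
`P(X_j = 1 | previous wave) = logistic(b_j + Σ_i W[i,j] X_i + γ_j·c)` —
the exact generative twin of the nodewise estimator, which is what makes
planted-support recovery a meaningful oracle.

What passing synthetic tests do **not** show: real symptom panels have
ordinal item structure, informative missingness, measurement
non-invariance and covariate-outcome dependence that the generator does
not emulate; results here validate the estimators' statistical behaviour
under the stated models, not robustness to those violations.

## Problem sizes and runtime choices

The suite and the reproduction script favour sizes that keep a single-CPU
run comfortable while leaving every statistical check at its stated
strength: synthetic cohorts of 4,000–5,000 subjects for enumeration (100
replicates for the BIC-selection check), n = 10,000 for network support
recovery, bootstrap B = 250, case-dropping at 20–50 subsamples per
proportion, and the BLRT level check at n = 150 with 99 bootstrap
replicates × 200 Monte-Carlo repetitions. The pipeline skips per-class
networks below 200 subjects and warns below 1,000 — small-class lagged
networks are exactly the regime where the case-dropping CS collapses, and
the package reproduces that collapse on synthetic nulls rather than
interpreting such networks.

## Known limitations

- The growth mixture assumes Gaussian within-class residuals on a
  lattice-valued observed scale; with very low item dispersion the
  discretization is visible to the information criteria.
- Lasso edge sets are support estimates, not tests; individual-edge
  significance is intentionally not reported (penalized CIs would be
  invalid for it).
- The trend test ignores the within-subject pairing of waves.
- Fit indices for the PP-LGCM use the normal-theory LR statistic; with
  strongly non-normal mean scores they inherit the usual caveats.
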