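# Methods

## Estimands and estimators

For refractive error Y (diopters; negative = myopia) and a binary risk
exposure X (1 = higher myopia risk), the package estimates

- the OLS coefficient of X — the population-average shift in Y, with
  classical standard errors and normal 95% intervals ("conventional"
  analysis);
- the conditional quantile coefficients β(τ) for τ on the 19-point grid
  0.05, 0.10, …, 0.95 — the shift in the τ-th conditional quantile of Y
  when exposed.

One model is fitted per risk factor (univariate plus optional
categorical covariates such as ethnicity dummies), never a joint
multivariable model, and complete cases are determined per factor, so
each factor's n reflects its own missingness. No age covariate is
included; ages are analysed as separate cross-sections and compared in
a second stage.

### Quantile regression

β(τ) minimizes the check (pinball) loss Σ ρ_τ(y_i − x_iᵀb) with
ρ_τ(u) = u(τ − 1{u<0}). The minimization is posed as the standard
linear program (residuals split into positive and negative parts) and
solved with scipy's HiGHS backend, which is deterministic and certifies
global optimality. Rank-deficient designs are rejected with the
offending columns named.

When the design is exactly an intercept plus one binary column, the
minimizer is available in closed form: the intercept is the check-loss
minimizing sample quantile of the unexposed group and the slope the
difference of group quantiles, using the order statistic at
⌈n·τ⌉ (the lower endpoint of the minimizing interval when n·τ is an
integer). `fit_cqr(method="auto")` uses this exact path — it minimizes
the identical objective — and the LP otherwise; the equality of the two
routes is covered by tests (achieved losses always; slopes wherever the
minimizer is unique). The resampling loops (bootstrap, permutation)
rely on this path for speed in the covariate-free case, which is what
makes simulation-based calibration checks run in seconds.

When the minimizer is not unique (n·τ integer producing a flat segment)
any minimizer may be returned; comparisons in tests then use achieved
loss rather than coefficients.

### Confidence intervals and p-values

OLS uses classical normal-theory intervals. For CQR the package uses
the case-resampling percentile bootstrap (default B = 500 in the
library, 200 in the pipeline): rows of the complete-case sample are
resampled with replacement and the model refitted; degenerate resamples
(single-level exposure, rank deficiency) are skipped and counted, with
more than 10% skips an error. The reported CQR p-value is a normal
approximation based on the bootstrap SE; the interval itself is
percentile-based. Rank-inversion or asymptotic-kernel intervals are
deliberate non-goals; the bootstrap was chosen because it applies
uniformly across the grid and under the saturated fast path.

## Permutation contrast of tail vs. median effects

The hypothesis β(τ) = β(0.50) is tested by permuting the exposure
column while holding the response and covariates fixed — the
exchangeable null of no exposure effect at any quantile — and
recomputing Δ* = β*(τ) − β*(0.50) per permutation. Both quantile levels
share each permuted dataset (paired contrast), which removes
between-replicate permutation noise from Δ*; an independent-permutation
mode is available. The two-sided p-value is
(1 + #{|Δ*| ≥ |Δ_obs|})/(B + 1), so p ≥ 1/(B+1) by construction.
In the covariate-free case the null is generated vectorized from group
order statistics; otherwise each permutation refits two LPs.

This label-permutation scheme tests the global null of no effect at any
quantile, with Δ as the test statistic; under a pure location shift
(effect present but equal across quantiles) it is not exact, and the
package documents rather than hides this assumption.

## Age-trend meta-regression

Per-age effect estimates (β_a, se_a) are combined by random-effects
meta-regression on age: a fixed-effect WLS fit with weights 1/se²
yields the residual heterogeneity statistic Q_E; the method-of-moments
(DerSimonian–Laird-type) heterogeneity variance is
τ² = max(0, (Q_E − (k − p))/tr(P)) with P the weighted residual
projector; the final slope (D/year) and its SE come from WLS with
weights 1/(se² + τ²), tested against a normal reference (no
Knapp–Hartung small-sample correction; k is 4–5 ages in practice and
the choice is documented rather than configurable away). With equal
SEs the slope reduces exactly to the unweighted least-squares slope
regardless of τ².

In the pipeline the per-age SEs are recovered from the stored 95%
intervals as (hi − lo)/(2·1.96) — exact for OLS, an approximation for
bootstrap percentile intervals.

## Loess profiles

Effect-vs-quantile profiles are smoothed by loess: at each grid point,
a weighted straight-line fit over the ⌈span·n⌉ nearest grid points with
tricube weights w = (1 − (d/d_max)³)³, endpoints using truncated
neighborhoods. Default span 0.75 on the 19-point grid, degree 1, which
reproduces exactly linear profiles exactly. The smoother is compared in
tests against an independent per-point weighted-fit implementation.

## Multiple imputation

Chained equations: missing cells are initialized by draws from each
column's observed margin, then updated sweep by sweep. Binary columns
are imputed by logistic regression (own Newton-IRLS with a tiny ridge
for stability under separation) with coefficients perturbed by a draw
from their approximate posterior; continuous columns by type-1
predictive mean matching (posterior-drawn predictions matched to k = 5
observed donors); `sample` draws from the margin. All other numeric
columns — always including the response, per standard MI guidance —
serve as predictors. Defaults m = 20 imputations and 10 sweeps in the
library (the pipeline uses m = 10, 5 sweeps by default for runtime);
observed cells are never modified and binary columns remain binary.

Per-imputation estimates are pooled by Rubin's rules: pooled β is the
mean, total variance W + (1 + 1/m)B with W the mean squared SE and B
the between-imputation variance, degrees of freedom
(m − 1)(1 + W/((1+1/m)B))², t-reference p-values. CQR estimates are
pooled using bootstrap SEs per imputation.

## Synthetic cohort generator

The generator exists so that every stage has a known truth. Refractive
error is drawn from the location-scale model

    Y = μ0 + Σ_j β_j(age)·X_j + σ0·exp(Σ_j γ_j(age)·X_j)·ε,

with exposures X_j independent Bernoulli(prevalence_j) drawn once per
subject and held fixed across ages, and ε standardized to mean 0,
variance 1. For a single active factor the true quantile effect is
exactly β + σ0(e^γ − 1)F_ε⁻¹(τ) (`true_quantile_effect`), which is the
oracle used throughout the tests; the closed form is refused for
configurations with several active factors.

Defaults and what they emulate:

- `error_shape="skew-normal"` with shape α = −4 (affinely standardized)
  gives the long myopic tail characteristic of refractive-error
  distributions in adolescence; `"normal"` is retained for analytic
  tests. α = −4 puts the standardized skewness near −0.8, a visibly
  asymmetric but unimodal distribution.
- β_j(age) = β_j(1 + s_j(age − min age)), and the same multiplier on
  γ_j: effects grow linearly with age, reproducing the observed
  monotone growth of tail effects across ages 7–15.
- `default_study_config` sets four factors at the prevalences reported
  for such cohorts (genetic risk 50%, parental myopia 59%, high reading
  37%, low outdoors 47%), median effects near −0.125 D, positive γ for
  tail amplification, and questionnaire missingness at 41.8%, 20.3%
  and 19.5%.
- μ0 = 0.2 D and σ0 = 1 D match the mean and spread of childhood
  refraction around age 7–10.

Missingness is injected MCAR (one rate per column) or MAR with the
missingness probability a two-level function of a named, fully observed
binary column. Ages are cross-sectionally independent within subject —
no within-subject correlation of the refraction residual across ages is
modelled, and no ocular biometry is simulated. Genotype panels are
independent variants under Hardy–Weinberg with dosages Binomial(2, maf)
and per-allele weights ~ N(0, 0.04²) D unless supplied.

What passing tests do and do not show: the generator matches the real
data in its marginal skewness, prevalences, missingness rates and the
location-scale form of effect heterogeneity, but real cohorts have
correlated exposures, measurement error (especially noncycloplegic
refraction), within-subject longitudinal correlation and
non-location-scale effect shapes; recovery results here validate the
estimators, not the epidemiology.

## Pipeline

`run_analysis` executes, per factor × age: complete-case OLS, the CQR
grid with bootstrap CIs, permutation contrasts of the configured tail
quantiles vs. τ_ref = 0.50, loess profiles (skipped with a logged
reason if the grid has fewer than 4 points), and, when enabled, an MI
branch (estimator suffix `-MI`). Age trends are fitted per factor and
estimator when ≥3 ages are present. Factors with fewer than two
exposure levels in an age group are skipped and logged. All
sub-stage seeds derive deterministically from the config seed, and the
config hash (SHA-256 over analysis-relevant fields, output paths
excluded) is written to `run.log`; reruns are byte-identical.
Outputs are tidy TSVs: `estimates.tsv` (factor, age_group, estimator,
tau, n, beta, ci_low, ci_high, p), `contrasts.tsv`, `trends.tsv`,
`profiles.tsv`, `demographics.tsv`.

No multiple-testing correction is applied anywhere; reported p-values
are nominal.

## Validation battery and problem sizes

`scripts/acceptance.py` (and the mirror tests in
`tests/test_acceptance.py`) recompute, from freshly simulated data:

- LP optimality vs. exhaustive exact-fit enumeration on 20 fixtures of
  n ≤ 12 (enumeration of all p-subsets covers every basic solution, so
  its minimum is the global one);
- the saturated-model identity on 100 datasets with odd group sizes
  (odd n makes the order-statistic quantile unique at τ ∈ {0.05, 0.25,
  0.5});
- closed-form recovery at n = 20,000 over 10 seeds (β = −0.125 D,
  γ = ln 2, normal ε: true tail effect −1.7699 D at τ = 0.05);
- tail amplification and OLS intermediacy under the skew-normal
  residual, 10 seeds;
- permutation calibration (500 null simulations, n = 1000, B = 199)
  and power (200 simulations, n = 2000, scale doubled);
- the meta-regression slope on four per-age OLS reading-effect
  estimates (−0.06, −0.10, −0.15, −0.21 D at ages 7, 10, 12, 15),
  whose equal-SE closed form is −0.65/34 ≈ −0.0191 D/yr;
- MI recovery under 30% MAR missingness on the exposure at n = 5000
  with m = 10, against the full-data estimates, plus the pooled-SE to
  complete-case-SE ratio;
- bootstrap coverage for the median-quantile effect (200 replicates,
  n = 2000, B = 500);
- byte-identity of rerun pipeline outputs.

These sizes were chosen so the whole battery completes in well under a
minute on one CPU while keeping Monte-Carlo bands near 3σ for each
stated tolerance.

## Known limitations

- The permutation scheme assumes exchangeability under the global null
  of no effect at any quantile (see above).
- CQR p-values are bootstrap-normal approximations, not rank-inversion.
- The MI engine is single-level with numeric predictors only
  (categorical covariates would need dummy expansion upstream) and
  offers no formal convergence diagnostics beyond determinism and the
  recovery tests.
- The generator's independence of ages within subject understates
  longitudinal correlation; trends across age are therefore estimated
  on effectively independent samples, which is the favorable case for
  the meta-regression.
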