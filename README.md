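# myopiaqr

Quantile-regression analysis of genetic and environmental risk factors
for refractive error in childhood cohorts.

## The problem

Conventional (OLS) regression of refractive error on a risk factor — a
high polygenic risk score, a myopic parent, much time reading, little
time outdoors — assumes the factor shifts every child's refraction by
the same amount. Conditional quantile regression (CQR) drops that
assumption: it estimates the effect β(τ) of the exposure on the τ-th
conditional quantile of refractive error, so an effect concentrated in
the myopic tail (low quantiles, negative diopters) becomes visible.
Large childhood cohort studies find exactly that pattern: risk-factor
effects several times larger at quantile 0.05 than at the median, which
is interpreted as emmetropization buffering most children against risk
exposure until its compensation limit is passed.

`myopiaqr` packages that analysis for epidemiologists who want to apply
or validate it without access to restricted cohort data:

- **phenotype coding** — mean spherical equivalent (SE = sphere +
  cyl/2, averaged over eyes), weighted polygenic risk scores with the
  center-then-binarize coding (1 = score below the mean), cohort
  questionnaire binarizations shipped as editable YAML rule files, and
  the per-parent myopia classification;
- **estimators** — OLS with classical intervals, and linear CQR by
  exact minimization of the check loss ρ_τ(u) = u(τ − 1{u<0}) via a
  linear program (HiGHS), across the 19-quantile grid τ = 0.05, 0.10,
  …, 0.95, with case-resampling bootstrap intervals;
- **second-stage inference** — permutation contrasts of β(τ) − β(0.50),
  random-effects meta-regression of effect size on age
  (method-of-moments heterogeneity), and loess smoothing of
  effect-vs-quantile profiles;
- **multiple imputation** — chained equations (logistic draws for
  binary columns, predictive mean matching for continuous) with Rubin
  pooling, mirroring the usual missing-questionnaire sensitivity
  analysis;
- **a synthetic-cohort generator** with known, quantile-varying effects:
  under the location-scale model
  `Y = μ0 + βX + σ0·exp(γX)·ε` (ε standardized, optionally
  skew-normal), the true quantile effect of a binary exposure is
  `β + σ0(e^γ − 1)F_ε⁻¹(τ)` in closed form, so every estimator in the
  package can be checked against an exact ground truth.

## Worked example

Simulate a cohort in which having a myopic parent shifts refraction by
−0.125 D and doubles the residual spread — so the median effect is
small but the tail effect is large — then estimate and test:

```python
import numpy as np
from myopiaqr import (
    SimulationConfig, FactorSpec, DesignSpec, simulate_cohort,
    true_quantile_effect, fit_cqr, fit_ols, permutation_quantile_contrast,
)

cfg = SimulationConfig(
    n_subjects=20_000,
    factors=(FactorSpec("parental_myopia", 0.59, beta=-0.125, gamma=np.log(2)),),
    seed=1, age_groups=(15.0,), mu0=-0.38, error_shape="normal",
)
cohort = simulate_cohort(cfg)
design = DesignSpec(exposure="parental_myopia")

for tau in (0.05, 0.50):
    fit = fit_cqr(cohort, design, tau)
    truth = true_quantile_effect(cfg, "parental_myopia", tau)
    print(f"CQR tau={tau:.2f}: beta = {fit.params['parental_myopia']:+.3f} D "
          f"(true {truth:+.3f} D, n = {fit.n})")
ols = fit_ols(cohort, design)
print(f"OLS:          beta = {ols.slope:+.3f} D (SE {ols.slope_se:.3f})")

contrast = permutation_quantile_contrast(cohort, design, 0.05, 0.50, n_perm=999, seed=2)
print(f"contrast beta(0.05)-beta(0.50) = {contrast.delta_obs:+.3f} D, "
      f"permutation p = {contrast.p:.3f}")
```

Output:

```
CQR tau=0.05: beta = -1.696 D (true -1.770 D, n = 20000)
CQR tau=0.50: beta = -0.098 D (true -0.125 D, n = 20000)
OLS:          beta = -0.094 D (SE 0.024)
contrast beta(0.05)-beta(0.50) = -1.599 D, permutation p = 0.001
```

The tail effect (−1.70 D at τ = 0.05) is an order of magnitude larger
than the median effect (−0.10 D); the OLS estimate sits between them
because it averages over the distribution; and the permutation test
rejects equality of the tail and median effects at its resolution limit
(p = 1/(B+1)).

The same analysis runs end to end from the command line:

```sh
myopiaqr all --config analysis.yaml --outdir out/
```

writing `estimates.tsv` (OLS + 19-quantile CQR per factor per age),
`contrasts.tsv`, `trends.tsv`, `profiles.tsv`, `demographics.tsv` and
`run.log`. Subcommands `simulate`, `code`, `fit`, `contrast`, `trend`
and `impute` expose the individual stages on the same TSV formats.

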