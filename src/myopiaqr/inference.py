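"""Second-stage inference on quantile-effect profiles.

Three procedures operate on fitted effect estimates:

* a permutation test contrasting the exposure effect at a tail quantile
  against the effect at the median (exchangeable null: the exposure
  labels carry no information at any quantile, so they are permuted
  while the response and covariates stay fixed);
* a random-effects meta-regression of effect size on age with a
  method-of-moments (DerSimonian-Laird-type) heterogeneity variance;
* loess smoothing (local linear, tricube weights) of effect-size
  profiles across the quantile grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quantreg import (
    DesignSpec,
    _is_saturated_binary,
    build_design,
    quantile_regression,
)

__all__ = [
    "PermutationComparison",
    "TrendResult",
    "EffectProfile",
    "permutation_quantile_contrast",
    "meta_regression_trend",
    "loess_smooth",
    "loess_profile",
]


@dataclass
class PermutationComparison:
    """Observed tail-vs-median contrast with its permutation p-value."""

    factor: str
    tau: float
    tau_ref: float
    delta_obs: float            # beta(tau) - beta(tau_ref), diopters
    n_perm: int
    p: float
    seed: int
    null_deltas: np.ndarray = field(repr=False, default=None)


@dataclass
class TrendResult:
    """Linear age trend of an effect size from random-effects meta-regression."""

    factor: str
    estimator: str              # "OLS" or "CQR@tau"
    slope: float                # diopters per year
    se: float
    p: float
    tau2: float                 # between-age heterogeneity variance


@dataclass
class EffectProfile:
    factor: str
    age_group: float
    taus: np.ndarray
    beta_raw: np.ndarray
    beta_smooth: np.ndarray
    span: float


def _tail_stats(values: np.ndarray, k: int) -> np.ndarray:
    """k-th order statistic along the last axis (1-based k)."""
    return np.partition(values, k - 1, axis=-1)[..., k - 1]


def _paired_null_fast(y, x, tau, tau_ref, n_perm, rng):
    """Vectorized permutation null for the covariate-free binary design.

    Each permutation reassigns the n1 exposure labels at random; the
    slope at a quantile is then the difference of group order-statistic
    quantiles, computed for both tau and tau_ref on the same permuted
    labels (paired contrast).
    """
    n = len(y)
    n1 = int(x.sum())
    n0 = n - n1
    k1_tau = max(1, math.ceil(n1 * tau))
    k0_tau = max(1, math.ceil(n0 * tau))
    k1_ref = max(1, math.ceil(n1 * tau_ref))
    k0_ref = max(1, math.ceil(n0 * tau_ref))
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    y1 = y[order[:, :n1]]
    y0 = y[order[:, n1:]]
    b_tau = _tail_stats(y1, k1_tau) - _tail_stats(y0, k0_tau)
    b_ref = _tail_stats(y1, k1_ref) - _tail_stats(y0, k0_ref)
    return b_tau - b_ref


def permutation_quantile_contrast(
    df: pd.DataFrame,
    design: DesignSpec,
    tau: float,
    tau_ref: float = 0.50,
    n_perm: int = 999,
    seed: int = 0,
    paired: bool = True,
    factor: str | None = None,
) -> PermutationComparison:
    """Permutation test of beta(tau) = beta(tau_ref).

    The observed contrast is computed from quantile fits at both levels
    on the complete cases; the null distribution permutes the exposure
    column (response and covariates fixed) and refits both quantiles per
    replicate.  With ``paired=True`` both levels share each permuted
    dataset, which removes between-replicate label noise from the
    contrast; ``paired=False`` draws independent permutations per level.
    Two-sided p = (1 + #{|delta*| >= |delta_obs|}) / (n_perm + 1).
    """
    if tau == tau_ref:
        raise ValueError("tau must differ from tau_ref")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    y, X, names = build_design(df, design)
    xcol = X[:, 1]
    if len(np.unique(xcol)) < 2:
        raise ValueError("constant exposure: no permutation distribution")
    rng = np.random.default_rng(seed)

    def slope(Xm, tau_):
        return float(quantile_regression(Xm, y, tau_, method="auto", check_rank=False)[1])

    delta_obs = slope(X, tau) - slope(X, tau_ref)

    fast = _is_saturated_binary(X)
    if fast and paired:
        null = _paired_null_fast(y, xcol, tau, tau_ref, n_perm, rng)
    elif fast:
        b_tau = _group_slopes_fast(y, xcol, tau, n_perm, rng)
        b_ref = _group_slopes_fast(y, xcol, tau_ref, n_perm, rng)
        null = b_tau - b_ref
    else:
        null = np.empty(n_perm)
        for b in range(n_perm):
            Xp = X.copy()
            Xp[:, 1] = rng.permutation(xcol)
            d = slope(Xp, tau) - slope(Xp, tau_ref)
            if not paired:
                Xp[:, 1] = rng.permutation(xcol)
                d = slope(Xp, tau) - float(
                    quantile_regression(Xp, y, tau_ref, method="auto", check_rank=False)[1]
                )
            null[b] = d
    p = (1.0 + np.sum(np.abs(null) >= abs(delta_obs))) / (n_perm + 1.0)
    return PermutationComparison(
        factor=factor or design.exposure, tau=tau, tau_ref=tau_ref,
        delta_obs=delta_obs, n_perm=n_perm, p=float(p), seed=seed, null_deltas=null,
    )


def _group_slopes_fast(y, x, tau, n_perm, rng):
    n, n1 = len(y), int(x.sum())
    n0 = n - n1
    k1 = max(1, math.ceil(n1 * tau))
    k0 = max(1, math.ceil(n0 * tau))
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    return _tail_stats(y[order[:, :n1]], k1) - _tail_stats(y[order[:, n1:]], k0)


def meta_regression_trend(
    betas, ses, ages, factor: str = "", estimator: str = ""
) -> TrendResult:
    """Random-effects meta-regression of effect size on age.

    Method-of-moments heterogeneity: fit fixed-effect WLS with weights
    1/se_i^2, compute the residual heterogeneity statistic Q_E, and set
    tau2 = max(0, (Q_E - (k - p)) / tr(P)) with P the weighted residual
    projector.  Final slope and its SE come from WLS with weights
    1/(se_i^2 + tau2); the two-sided p uses a normal reference.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    a = np.asarray(ages, dtype=float)
    if len(b) < 3:
        raise ValueError("need at least 3 age points for a trend")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    k = len(b)
    X = np.column_stack([np.ones(k), a])
    p_dim = X.shape[1]

    W = np.diag(1.0 / s**2)
    XtWX_inv = np.linalg.inv(X.T @ W @ X)
    beta_fe = XtWX_inv @ X.T @ W @ b
    resid = b - X @ beta_fe
    Q_E = float(resid @ W @ resid)
    P = W - W @ X @ XtWX_inv @ X.T @ W
    trP = float(np.trace(P))
    tau2 = max(0.0, (Q_E - (k - p_dim)) / trP) if trP > 0 else 0.0

    Wr = np.diag(1.0 / (s**2 + tau2))
    cov = np.linalg.inv(X.T @ Wr @ X)
    beta_re = cov @ X.T @ Wr @ b
    slope = float(beta_re[1])
    se = float(np.sqrt(cov[1, 1]))
    z = slope / se if se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z)) if se > 0 else 1.0
    return TrendResult(factor=factor, estimator=estimator, slope=slope, se=se,
                       p=float(p), tau2=float(tau2))


def _tricube(u):
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess_smooth(x, y, span: float = 0.75, degree: int = 1) -> np.ndarray:
    """Loess: local polynomial fit with tricube weights, evaluated at each x.

    The neighborhood of each evaluation point contains ceil(span * n)
    nearest points; endpoints use the same rule and hence truncated,
    asymmetric neighborhoods.  Degree-1 (local linear) reproduces exactly
    linear input exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < degree + 3:
        raise ValueError("too few points to smooth")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0,1]")
    q = int(math.ceil(span * n))
    if q < degree + 2:
        raise ValueError("span too small for local fits")
    out = np.empty(n)
    for i, x0 in enumerate(x):
        d = np.abs(x - x0)
        dq = np.sort(d)[q - 1]
        if dq == 0:
            dq = np.finfo(float).eps
        w = _tricube(d / dq)
        active = w > 0
        Xl = np.vander(x[active] - x0, degree + 1, increasing=True)
        Wl = w[active]
        XtW = Xl.T * Wl
        coef = np.linalg.solve(XtW @ Xl, XtW @ y[active])
        out[i] = coef[0]
    return out


def loess_profile(
    taus, betas, span: float = 0.75, factor: str = "", age_group: float = float("nan")
) -> EffectProfile:
    """Smooth an effect-size-vs-quantile profile on its own grid."""
    taus = np.asarray(taus, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if len(taus) < 4:
        raise ValueError("need at least 4 grid points")
    smooth = loess_smooth(taus, betas, span=span, degree=1)
    return EffectProfile(factor=factor, age_group=age_group, taus=taus,
                         beta_raw=betas, beta_smooth=smooth, span=span)
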