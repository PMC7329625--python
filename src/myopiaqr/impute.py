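"""Multiple imputation by chained equations with Rubin-rule pooling.

Missing exposures/covariates are filled by iterated conditional draws:
binary columns by logistic regression with posterior-perturbed
coefficients, continuous columns by predictive mean matching (type-1,
k-donor), or by sampling from the observed margin.  Imputation models
always include the response among the predictors, per standard MI
guidance for congeniality with the analysis model.  Estimates fitted on
the m completed tables are combined with Rubin's rules (within-variance
W, between-variance B, total variance W + (1 + 1/m) B, Barnard-Rubin
style degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .quantreg import DesignSpec, bootstrap_ci, fit_cqr, fit_ols

__all__ = [
    "ImputationConfig",
    "PooledEstimate",
    "mice_impute",
    "pool_rubin",
    "pool_analysis",
]


@dataclass(frozen=True)
class ImputationConfig:
    """Chained-equation settings.

    ``methods`` maps each incompletely observed column to one of
    ``"logistic"`` (binary), ``"pmm"`` (continuous, predictive mean
    matching with ``pmm_donors`` donors) or ``"sample"`` (draw from the
    observed margin).
    """

    methods: dict
    m: int = 20
    n_iter: int = 10
    seed: int = 0
    pmm_donors: int = 5

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class PooledEstimate:
    """Rubin-pooled coefficient across m imputations."""

    beta: float
    se: float
    within: float               # W = mean of squared SEs
    between: float              # B = variance of point estimates
    m: int
    df: float
    p: float


def _logistic_fit(X, y, ridge=1e-8, max_iter=100):
    """Newton-IRLS logistic regression; returns (beta_hat, covariance).

    A tiny ridge keeps the Hessian invertible under separation or
    collinearity in the imputation model.
    """
    n, p = X.shape
    beta = np.zeros(p)
    H = np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        H = (X.T * w) @ X + ridge * np.eye(p)
        grad = X.T @ (y - mu) - ridge * beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta, np.linalg.inv(H)


def _predictor_matrix(df: pd.DataFrame, target: str, numeric_cols) -> np.ndarray:
    cols = [c for c in numeric_cols if c != target]
    X = df[cols].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), X])


def _draw_logistic(X_obs, y_obs, X_mis, rng):
    beta_hat, cov = _logistic_fit(X_obs, y_obs)
    beta_star = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    p_mis = expit(np.clip(X_mis @ beta_star, -30, 30))
    return (rng.random(len(p_mis)) < p_mis).astype(float)


def _draw_pmm(X_obs, y_obs, X_mis, rng, k):
    """Type-1 predictive mean matching: posterior-draw predictions for the
    missing rows, least-squares predictions for the observed rows, match
    to the k nearest observed donors and sample one."""
    n, p = X_obs.shape
    XtX = X_obs.T @ X_obs + 1e-10 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - p, 1)
    sigma2_star = float(resid @ resid) / rng.chisquare(dof)
    cov = sigma2_star * np.linalg.inv(XtX)
    beta_star = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_star
    k = min(k, n)
    out = np.empty(len(pred_mis))
    for i, pm in enumerate(pred_mis):
        nearest = np.argpartition(np.abs(pred_obs - pm), k - 1)[:k]
        out[i] = y_obs[nearest[rng.integers(k)]]
    return out


def mice_impute(table: pd.DataFrame, config: ImputationConfig) -> list[pd.DataFrame]:
    """Produce m completed copies of the table.

    Only columns listed in ``config.methods`` are imputed; every column
    containing missing values must be listed.  Observed cells are
    unchanged in all m outputs; binary columns stay in {0, 1}; results
    are deterministic given the seed.  A table with no missing values
    yields m identical copies.
    """
    targets = [c for c in config.methods if table[c].isna().any()]
    undeclared = [
        c for c in table.columns
        if table[c].isna().any() and c not in config.methods
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    if undeclared:
        raise ValueError(f"columns with missing values lack a method: {undeclared}")
    for c in targets:
        if table[c].isna().all():
            raise ValueError(f"column {c!r} is fully missing; cannot impute")
    numeric_cols = [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    if not any(table[c].notna().all() for c in numeric_cols):
        raise ValueError("need at least one fully observed numeric column")

    root = np.random.default_rng(config.seed)
    seeds = root.integers(2**31 - 1, size=config.m)
    completed = []
    for m_idx in range(config.m):
        rng = np.random.default_rng(seeds[m_idx])
        work = table.copy()
        if not targets:
            completed.append(work)
            continue
        # initialize by sampling from each column's observed margin
        for c in targets:
            miss = work[c].isna()
            obs_vals = work.loc[~miss, c].to_numpy(dtype=float)
            work.loc[miss, c] = rng.choice(obs_vals, size=miss.sum())
        for _ in range(config.n_iter):
            for c in targets:
                miss = table[c].isna().to_numpy()
                X = _predictor_matrix(work, c, numeric_cols)
                y_obs = table.loc[~miss, c].to_numpy(dtype=float)
                X_obs, X_mis = X[~miss], X[miss]
                method = config.methods[c]
                if method == "logistic":
                    draw = _draw_logistic(X_obs, y_obs, X_mis, rng)
                elif method == "pmm":
                    draw = _draw_pmm(X_obs, y_obs, X_mis, rng, config.pmm_donors)
                elif method == "sample":
                    draw = rng.choice(y_obs, size=miss.sum())
                else:
                    raise ValueError(f"unknown method {method!r} for column {c!r}")
                work.loc[miss, c] = draw
        completed.append(work)
    return completed


def pool_rubin(betas, ses) -> PooledEstimate:
    """Combine per-imputation estimates with Rubin's rules."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    m = len(b)
    if m < 2:
        raise ValueError("need at least 2 imputations to pool")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    qbar = float(b.mean())
    W = float(np.mean(s**2))
    B = float(b.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    se = float(np.sqrt(T))
    if B > 0:
        df = (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2
        p = 2.0 * stats.t.sf(abs(qbar / se), df)
    else:
        df = np.inf
        p = 2.0 * stats.norm.sf(abs(qbar / se)) if se > 0 else 1.0
    return PooledEstimate(beta=qbar, se=se, within=W, between=B, m=m,
                          df=float(df), p=float(p))


def pool_analysis(
    tables: list[pd.DataFrame],
    design: DesignSpec,
    estimator: str = "OLS",
    tau: float | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> PooledEstimate:
    """Fit the analysis model on each completed table and Rubin-pool.

    OLS uses classical standard errors per imputation; CQR uses the
    case-resampling bootstrap SE per imputation.
    """
    betas, ses = [], []
    for i, t in enumerate(tables):
        if estimator == "OLS":
            fit = fit_ols(t, design)
            betas.append(fit.slope)
            ses.append(fit.slope_se)
        elif estimator == "CQR":
            fit = fit_cqr(t, design, tau)
            boot = bootstrap_ci(t, design, "CQR", tau=tau, n_boot=n_boot, seed=seed + i)
            betas.append(fit.slope)
            ses.append(boot.se)
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
    return pool_rubin(betas, ses)
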