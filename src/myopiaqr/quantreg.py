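"""OLS and linear conditional quantile regression, from first principles.

The quantile estimator minimizes the check (pinball) loss

    rho_tau(u) = u * (tau - 1{u < 0}),

formulated as a linear program (residuals split into positive and
negative parts) and solved with scipy's deterministic HiGHS backend, so
every fit carries a global-optimality certificate.  For the frequent
special case of an intercept plus a single binary exposure and no other
covariates, the minimizer is available in closed form as the pair of
group order-statistic quantiles; ``method="auto"`` uses that exact path
(it minimizes the identical objective) and falls back to the LP whenever
covariates are present.  Confidence intervals for quantile coefficients
use the case-resampling percentile bootstrap; OLS uses classical
normal-theory intervals to mirror a conventional analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

__all__ = [
    "DesignSpec",
    "QuantileGrid",
    "EffectEstimate",
    "pinball_loss",
    "check_quantile",
    "group_quantile_oracle",
    "quantile_regression",
    "fit_cqr",
    "fit_ols",
    "fit_cqr_grid",
    "bootstrap_ci",
    "build_design",
]

DEFAULT_TAUS = tuple(np.round(np.arange(1, 20) * 0.05, 2))


@dataclass(frozen=True)
class DesignSpec:
    """Model specification: response ~ exposure (+ categorical covariates).

    One model per risk factor; covariates (e.g. ethnicity for a mixed
    cohort) enter as dummy columns.  Only complete cases on the involved
    columns are fitted.
    """

    response: str = "refractive_error"
    exposure: str = "exposure"
    covariates: tuple[str, ...] = ()


@dataclass(frozen=True)
class QuantileGrid:
    """Ordered quantile levels; default is the 19-point grid 0.05..0.95."""

    taus: tuple[float, ...] = DEFAULT_TAUS

    def __post_init__(self):
        t = np.asarray(self.taus, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("grid must be a non-empty 1-d sequence")
        if np.any(t <= 0) or np.any(t >= 1) or np.any(np.diff(t) <= 0):
            raise ValueError("taus must be strictly increasing within (0,1)")


@dataclass
class EffectEstimate:
    """One (factor x age x estimator x quantile) coefficient."""

    factor: str
    age_group: float
    estimator: str              # "OLS" or "CQR"
    tau: float | None
    beta: float
    ci_low: float
    ci_high: float
    p: float
    n: int


class RankDeficientError(np.linalg.LinAlgError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


def pinball_loss(residuals, tau: float) -> float:
    """Total check loss sum_i u_i (tau - 1{u_i < 0}); zero iff all residuals are zero."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0,1)")
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def check_quantile(values, tau: float) -> float:
    """Sample tau-quantile as the order statistic at ceil(n*tau).

    This convention picks a minimizer of the check loss (the lower
    endpoint of the minimizing interval when n*tau is an integer) and is
    the same convention the saturated-model fast path and the group
    oracle use.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        raise ValueError("empty sample")
    k = max(1, math.ceil(n * tau))
    return float(np.partition(v, k - 1)[k - 1])


def group_quantile_oracle(y, x, tau: float) -> float:
    """Difference of group sample quantiles Q_tau(y|x=1) - Q_tau(y|x=0).

    For a saturated model (intercept + one binary covariate) this equals
    the check-loss-minimizing slope; used as an independent oracle.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x)
    y1, y0 = y[x == 1], y[x == 0]
    if len(y1) == 0 or len(y0) == 0:
        raise ValueError("both exposure groups must be non-empty")
    return check_quantile(y1, tau) - check_quantile(y0, tau)


def _independent_columns(X: np.ndarray):
    """Greedy maximal independent column set; returns (kept, dropped) indices."""
    kept, dropped = [], []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            dropped.append(j)
    return kept, dropped


def _check_rank(X: np.ndarray, names):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, dropped = _independent_columns(X)
        raise RankDeficientError([names[j] for j in dropped])


def _is_saturated_binary(X: np.ndarray) -> bool:
    """True when X is exactly [intercept, binary column] (either order)."""
    if X.shape[1] != 2:
        return False
    for j, k in ((0, 1), (1, 0)):
        col_int, col_x = X[:, j], X[:, k]
        if np.all(col_int == 1.0) and np.isin(col_x, (0.0, 1.0)).all():
            if 0 < col_x.sum() < len(col_x):
                return True
    return False


def _saturated_binary_solution(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    int_first = np.all(X[:, 0] == 1.0) and np.isin(X[:, 1], (0.0, 1.0)).all() \
        and 0 < X[:, 1].sum() < len(y)
    xcol = X[:, 1] if int_first else X[:, 0]
    q0 = check_quantile(y[xcol == 0], tau)
    q1 = check_quantile(y[xcol == 1], tau)
    beta = np.array([q0, q1 - q0])
    return beta if int_first else beta[::-1]


def _lp_quantile_regression(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    n, p = X.shape
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    A_eq = sparse.hstack(
        [sparse.csr_matrix(X), sparse.eye(n, format="csr"), -sparse.eye(n, format="csr")],
        format="csr",
    )
    bounds = [(None, None)] * p + [(0.0, None)] * (2 * n)
    res = optimize.linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile-regression LP failed: {res.message}")
    return res.x[:p]


def quantile_regression(
    X, y, tau: float, method: str = "auto", check_rank: bool = True, names=None
) -> np.ndarray:
    """Minimize the check loss of y - X b; returns the coefficient vector.

    ``method="lp"`` always solves the linear program; ``"auto"`` uses the
    exact closed-form solution when the design is an intercept plus one
    binary column.  Both routes minimize the same objective.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0,1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-d with one row per observation")
    if len(y) <= X.shape[1]:
        raise ValueError("need more complete cases than parameters")
    if check_rank:
        _check_rank(X, names if names is not None else list(range(X.shape[1])))
    if method == "auto" and _is_saturated_binary(X):
        return _saturated_binary_solution(X, y, tau)
    if method not in ("auto", "lp"):
        raise ValueError(f"unknown method {method!r}")
    return _lp_quantile_regression(X, y, tau)


def build_design(df: pd.DataFrame, design: DesignSpec):
    """Complete-case response vector and design matrix for one model.

    Returns ``(y, X, names)`` where X has an intercept first, the binary
    exposure second, then dummy columns (first level dropped) for each
    categorical covariate.  Rows with any missing value in the involved
    columns are excluded, so each risk factor gets its own complete-case
    sample.
    """
    cols = [design.response, design.exposure, *design.covariates]
    for c in cols:
        if c not in df.columns:
            raise KeyError(f"column {c!r} not in table")
    sub = df[cols].dropna()
    y = sub[design.response].to_numpy(dtype=float)
    parts = [np.ones(len(sub)), sub[design.exposure].to_numpy(dtype=float)]
    names = ["intercept", design.exposure]
    for cov in design.covariates:
        dummies = pd.get_dummies(sub[cov], prefix=cov, drop_first=True)
        for cname in dummies.columns:
            parts.append(dummies[cname].to_numpy(dtype=float))
            names.append(str(cname))
    X = np.column_stack(parts)
    return y, X, names


@dataclass
class CQRFit:
    params: pd.Series
    loss: float
    n: int

    @property
    def slope(self) -> float:
        return float(self.params.iloc[1])


def fit_cqr(df: pd.DataFrame, design: DesignSpec, tau: float, method: str = "auto") -> CQRFit:
    """Fit one conditional quantile regression on the complete cases."""
    y, X, names = build_design(df, design)
    beta = quantile_regression(X, y, tau, method=method, names=names)
    loss = pinball_loss(y - X @ beta, tau)
    return CQRFit(params=pd.Series(beta, index=names), loss=loss, n=len(y))


@dataclass
class OLSFit:
    params: pd.Series
    se: pd.Series
    n: int

    @property
    def slope(self) -> float:
        return float(self.params.iloc[1])

    @property
    def slope_se(self) -> float:
        return float(self.se.iloc[1])


def _ols_arrays(X: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov))


def fit_ols(df: pd.DataFrame, design: DesignSpec) -> OLSFit:
    """Ordinary least squares with classical standard errors."""
    y, X, names = build_design(df, design)
    if len(y) <= X.shape[1]:
        raise ValueError("need more complete cases than parameters")
    _check_rank(X, names)
    beta, se = _ols_arrays(X, y)
    return OLSFit(
        params=pd.Series(beta, index=names), se=pd.Series(se, index=names), n=len(y)
    )


def ols_effect(df: pd.DataFrame, design: DesignSpec, factor: str, age_group: float) -> EffectEstimate:
    """OLS exposure coefficient with normal-theory 95% CI and two-sided p."""
    fit = fit_ols(df, design)
    b, s = fit.slope, fit.slope_se
    z = stats.norm.ppf(0.975)
    p = 2.0 * stats.norm.sf(abs(b / s)) if s > 0 else (1.0 if b == 0 else 0.0)
    return EffectEstimate(
        factor=factor, age_group=age_group, estimator="OLS", tau=None,
        beta=b, ci_low=b - z * s, ci_high=b + z * s, p=p, n=fit.n,
    )


@dataclass
class BootstrapResult:
    ci_low: float
    ci_high: float
    se: float
    draws: np.ndarray = field(repr=False)
    n_skipped: int = 0


def bootstrap_ci(
    df: pd.DataFrame,
    design: DesignSpec,
    estimator: str = "CQR",
    tau: float | None = None,
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapResult:
    """Case-resampling percentile bootstrap for the exposure coefficient.

    Resamples complete-case rows with replacement and refits; degenerate
    resamples (single-level exposure or rank-deficient design) are
    skipped and counted, and more than 10% skips is an error.  ``se`` is
    the standard deviation of the bootstrap coefficient draws.
    Deterministic for a given seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if estimator == "CQR" and tau is None:
        raise ValueError("CQR bootstrap requires tau")
    y, X, names = build_design(df, design)
    _check_rank(X, names)
    rng = np.random.default_rng(seed)
    n = len(y)
    fast = estimator == "CQR" and _is_saturated_binary(X)
    xcol = X[:, 1] if fast else None
    draws, skipped = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if fast:
            xb = xcol[idx]
            s = xb.sum()
            if s == 0 or s == n:
                skipped += 1
                continue
            draws.append(check_quantile(yb[xb == 1], tau) - check_quantile(yb[xb == 0], tau))
            continue
        Xb = X[idx]
        try:
            if estimator == "CQR":
                beta = quantile_regression(Xb, yb, tau, method="auto", check_rank=True)
            else:
                _check_rank(Xb, names)
                beta, _ = _ols_arrays(Xb, yb)
        except (np.linalg.LinAlgError, ValueError):
            skipped += 1
            continue
        draws.append(float(beta[1]))
    if skipped > 0.1 * n_boot:
        raise RuntimeError(f"{skipped}/{n_boot} bootstrap refits degenerate")
    draws = np.asarray(draws)
    alpha = 1.0 - level
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapResult(
        ci_low=float(lo), ci_high=float(hi),
        se=float(draws.std(ddof=1)), draws=draws, n_skipped=skipped,
    )


def cqr_effect(
    df: pd.DataFrame,
    design: DesignSpec,
    tau: float,
    factor: str,
    age_group: float,
    n_boot: int = 500,
    seed: int = 0,
) -> EffectEstimate:
    """CQR exposure coefficient with bootstrap percentile CI.

    The two-sided p-value is a normal approximation based on the
    bootstrap standard error (the interval itself is percentile-based).
    """
    fit = fit_cqr(df, design, tau)
    boot = bootstrap_ci(df, design, "CQR", tau=tau, n_boot=n_boot, seed=seed)
    b = fit.slope
    if boot.se > 0:
        p = 2.0 * stats.norm.sf(abs(b / boot.se))
    else:
        p = 1.0 if b == 0 else 0.0
    return EffectEstimate(
        factor=factor, age_group=age_group, estimator="CQR", tau=tau,
        beta=b, ci_low=boot.ci_low, ci_high=boot.ci_high, p=p, n=fit.n,
    )


def fit_cqr_grid(
    df: pd.DataFrame,
    design: DesignSpec,
    grid: QuantileGrid = QuantileGrid(),
    factor: str = "exposure",
    age_group: float = float("nan"),
    n_boot: int = 500,
    seed: int = 0,
) -> list[EffectEstimate]:
    """One CQR fit per grid quantile on the identical complete-case sample."""
    estimates = []
    for i, tau in enumerate(grid.taus):
        estimates.append(
            cqr_effect(df, design, tau, factor, age_group, n_boot=n_boot, seed=seed + i)
        )
    return estimates


def estimates_to_frame(estimates) -> pd.DataFrame:
    """Tidy table of effect estimates (the machine-readable effects table)."""
    rows = [
        {
            "factor": e.factor, "age_group": e.age_group, "estimator": e.estimator,
            "tau": e.tau if e.tau is not None else "",
            "n": e.n, "beta": e.beta, "ci_low": e.ci_low, "ci_high": e.ci_high, "p": e.p,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)
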