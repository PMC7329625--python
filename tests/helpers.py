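"""Independent brute-force oracles shared across test modules."""

from itertools import combinations

import numpy as np

from myopiaqr.quantreg import pinball_loss


def exhaustive_cqr_minimum(X, y, tau):
    """Global minimum of the check loss by exhaustive enumeration.

    A minimizer of the piecewise-linear check loss can always be chosen
    to interpolate p observations exactly (a basic solution of the
    equivalent linear program), so enumerating every p-subset of rows,
    solving the exact-fit coefficients, and evaluating the loss yields
    the global optimum.  Independent of the LP solver under test.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    best_loss, best_beta = np.inf, None
    for rows in combinations(range(n), p):
        sub = X[list(rows)]
        if abs(np.linalg.det(sub)) < 1e-12:
            continue
        beta = np.linalg.solve(sub, y[list(rows)])
        loss = pinball_loss(y - X @ beta, tau)
        if loss < best_loss:
            best_loss, best_beta = loss, beta
    return best_loss, best_beta


def naive_prs(weights, dosages):
    """Double-loop weighted allele count, the obvious quadratic oracle."""
    n_var, n_sub = dosages.shape
    out = np.zeros(n_sub)
    for s in range(n_sub):
        for v in range(n_var):
            out[s] += weights[v] * dosages[v, s]
    return out


def direct_local_linear(x, y, x0, weights):
    """One weighted straight-line fit evaluated at x0, via lstsq."""
    W = np.sqrt(weights)
    A = np.column_stack([np.ones_like(x), x - x0]) * W[:, None]
    coef, *_ = np.linalg.lstsq(A, y * W, rcond=None)
    return coef[0]
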