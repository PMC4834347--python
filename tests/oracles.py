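"""Independent reference implementations used to check the package.

These deliberately avoid the code paths they validate: the elastic-net
oracle is a generic bound-constrained optimizer on the split-variable
(β = β⁺ − β⁻) formulation, AUC is a direct pair count, and univariate
logistic p-values come from statsmodels.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def enet_objective(y, X, Z, theta, alpha, lam, penalize_intercept=False):
    """Penalized objective (minimization form) evaluated directly."""
    q = 0 if Z is None else Z.shape[1]
    c = theta[0]
    g = theta[1:1 + q]
    b = theta[1 + q:]
    eta = c + (Z @ g if q else 0.0) + X @ b
    nll = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
    pen_terms = np.concatenate([[c], b]) if penalize_intercept else b
    pen = lam * (0.5 * (1 - alpha) * np.sum(pen_terms**2)
                 + alpha * np.sum(np.abs(pen_terms)))
    return nll + float(pen)


def enet_oracle_objective(y, X, Z, alpha, lam, penalize_intercept=False):
    """Optimal objective value via L-BFGS-B on the split-variable form."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    q = 0 if Z is None else Z.shape[1]

    def obj(u):
        if penalize_intercept:
            cp, cm = u[0], u[1]
            c = cp - cm
            g = u[2:2 + q]
            bp = u[2 + q:2 + q + p]
            bm = u[2 + q + p:]
            pen_abs = cp + cm + np.sum(bp + bm)
            pen_sq = c**2 + np.sum((bp - bm) ** 2)
        else:
            c = u[0]
            g = u[1:1 + q]
            bp = u[1 + q:1 + q + p]
            bm = u[1 + q + p:]
            pen_abs = np.sum(bp + bm)
            pen_sq = np.sum((bp - bm) ** 2)
        b = bp - bm
        eta = c + (Z @ g if q else 0.0) + X @ b
        nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
        return nll + lam * (0.5 * (1 - alpha) * pen_sq + alpha * pen_abs)

    n_free = (2 if penalize_intercept else 1) + q
    x0 = np.zeros(n_free + 2 * p)
    bounds = (
        ([(0, None)] * 2 if penalize_intercept else [(None, None)])
        + [(None, None)] * q
        + [(0, None)] * (2 * p)
    )
    res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 10000, "ftol": 1e-15, "gtol": 1e-11})
    return float(res.fun)


def auc_by_pair_count(scores, labels) -> float:
    """AUC as the fraction of (case, control) pairs ranked correctly (ties ½)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def statsmodels_lrt_pvalue(x, y, Z=None) -> float:
    """Likelihood-ratio p-value for one feature via statsmodels Logit."""
    import statsmodels.api as sm
    from scipy import stats

    n = len(y)
    base = np.ones((n, 1)) if Z is None else np.column_stack([np.ones(n), Z])
    full = np.column_stack([base, x])
    with np.errstate(all="ignore"):
        ll0 = sm.Logit(y, base).fit(disp=0, method="newton", maxiter=100).llf
        ll1 = sm.Logit(y, full).fit(disp=0, method="newton", maxiter=100).llf
    return float(stats.chi2.sf(max(2 * (ll1 - ll0), 0.0), 1))


def brute_force_separating_subsets(X, y, Z, k, margin=1e-6):
    """All size-k separating subsets by exhaustive LP over normalized data."""
    import itertools

    from mmsig._linsep import find_strict_separator

    def norm(cols):
        c = cols.mean(axis=0)
        s = cols.std(axis=0)
        return (cols - c) / np.where(s == 0, 1.0, s)

    p = X.shape[1]
    out = []
    for combo in itertools.combinations(range(p), k):
        cols = norm(X[:, list(combo)])
        if Z is not None:
            cols = np.column_stack([cols, norm(Z)])
        if find_strict_separator(cols, y, margin)[0]:
            out.append(combo)
    return out
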