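"""Linear-feasibility test for strict (perfect) separation.

Maximum-likelihood logistic fits diverge when the two classes are linearly
separable, so "a logistic model achieves perfect separation" is
operationalized as "a strict linear separator exists", decided by a linear
program: find coefficients w (sup-norm ≤ 1) and intercept b with
``s_i (w·x_i + b) ≥ margin`` for every subject, where s_i = ±1 encodes the
class.  Columns should be normalized by the caller so the fixed margin is
meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def find_strict_separator(
    X: np.ndarray, labels: np.ndarray, margin: float = 1e-6
) -> tuple[bool, np.ndarray | None, float | None]:
    """Return (separable, w, b); w/b are None when infeasible."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    s = 2.0 * np.asarray(labels, dtype=float) - 1.0
    n, d = X.shape
    A_ub = -(s[:, None] * np.column_stack([X, np.ones(n)]))
    b_ub = np.full(n, -margin)
    res = linprog(
        c=np.zeros(d + 1),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(-1.0, 1.0)] * (d + 1),
        method="highs",
    )
    if res.status == 0:
        return True, res.x[:d], float(res.x[d])
    return False, None, None


def is_separable(X: np.ndarray, labels: np.ndarray, margin: float = 1e-6) -> bool:
    return find_strict_separator(X, labels, margin)[0]


def separation_holds(
    X: np.ndarray, labels: np.ndarray, w: np.ndarray, b: float
) -> bool:
    """Check strictly correct classification of every row by (w, b)."""
    s = 2.0 * np.asarray(labels, dtype=float) - 1.0
    return bool(np.all(s * (np.asarray(X, float) @ np.asarray(w, float) + b) > 0))
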