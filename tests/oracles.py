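"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths of the package under test: t tails
come from the closed-form regularized incomplete beta, BH is a literal
step-up loop, OLS solves the normal equations directly, the permutation FDR
enumerates relabelings with plain Python loops, and overlaps are counted by
double iteration.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.special import betainc


def t_right_tail(t: float, df: float) -> float:
    """P(T > t) for Student's t via the incomplete-beta closed form."""
    if not np.isfinite(t):
        return 0.0 if t > 0 else 1.0
    x = df / (df + t * t)
    half = 0.5 * betainc(df / 2.0, 0.5, x)
    return half if t >= 0 else 1.0 - half


def t_two_sided(t: float, df: float) -> float:
    return 2.0 * t_right_tail(abs(t), df)


def welch_pieces(a, b):
    """(diff, se, df) of the Welch two-sample statistic, scalar arithmetic."""
    a, b = list(map(float, a)), list(map(float, b))
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    q1, q2 = v1 / n1, v2 / n2
    se = (q1 + q2) ** 0.5
    df = (q1 + q2) ** 2 / (q1**2 / (n1 - 1) + q2**2 / (n2 - 1))
    return m1 - m2, se, df


def bh_stepup(p):
    """Benjamini–Hochberg adjusted p-values by the literal definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def ols_normal_equations(X, y):
    """OLS via the normal equations: beta, se, sigma2, cov."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(xtx)
    return beta, np.sqrt(np.diag(cov)), sigma2, cov


def sam_d(a, b, s0):
    diff, se, _ = welch_pieces(a, b)
    return diff / (se + s0)


def exhaustive_perm_fdr(data: np.ndarray, n1: int, s0: float,
                        candidates) -> list[float]:
    """Estimated FDR at each candidate threshold over ALL relabelings.

    ``data`` is proteins x (n1 + n2) pooled columns; group 1 is every
    ``n1``-subset of the columns (identity labeling included).
    """
    n = data.shape[1]
    d_obs = [sam_d(row[:n1], row[n1:], s0) for row in data]
    perms = []
    for grp1 in combinations(range(n), n1):
        grp2 = [j for j in range(n) if j not in grp1]
        perms.append([sam_d(row[list(grp1)], row[grp2], s0) for row in data])
    fdrs = []
    for c in candidates:
        obs = sum(1 for d in d_obs if d >= c)
        mean_exceed = np.mean([sum(1 for d in perm if d >= c) for perm in perms])
        fdrs.append(mean_exceed / obs if obs else float("inf"))
    return fdrs


def overlap_bruteforce(sets: dict):
    """{(row, col): (numerator, denominator)} by double iteration."""
    out = {}
    for r, sr in sets.items():
        for c, sc in sets.items():
            inter = sum(1 for x in set(sr) if x in set(sc))
            out[(r, c)] = (inter, len(set(sr)))
    return out


def pca_scores_eigh(X: np.ndarray) -> np.ndarray:
    """Sample scores from an explicit covariance eigendecomposition."""
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return Xc @ v[:, order]
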