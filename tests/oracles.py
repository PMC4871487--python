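"""Independent oracles used by the test suite.

These deliberately avoid the package's solver paths: the lasso oracle
enumerates sign-pattern-constrained quadratic programs, the truncated-normal
oracle integrates the Gaussian density numerically, and the permutation
oracle recomputes error changes gene by gene with explicit loops.
"""

from itertools import product

import numpy as np
from scipy import integrate, stats


def lasso_signpattern_minimum(X, y, lam):
    """Global lasso minimum by exhaustive search over sign patterns.

    Solves, for every sign pattern s in {-1,0,1}^p, the stationary point of
    (1/2n)||yc - Xc w||^2 + lam * s' w restricted to the support of s, keeps
    the sign-feasible ones, and returns (best objective, best support set).
    The lasso solution's own pattern is always feasible, so the minimum over
    feasible stationary points is the global lasso minimum.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()

    def objective(w):
        return 0.5 * np.mean((yc - Xc @ w) ** 2) + lam * np.abs(w).sum()

    best = objective(np.zeros(p))
    best_support = frozenset()
    for s in product((-1, 0, 1), repeat=p):
        s = np.array(s, float)
        idx = np.flatnonzero(s != 0)
        if idx.size == 0:
            continue
        Xs = Xc[:, idx]
        G = Xs.T @ Xs / n
        rhs = Xs.T @ yc / n - lam * s[idx]
        try:
            ws = np.linalg.solve(G, rhs)
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.sign(ws) == s[idx]):
            continue
        w = np.zeros(p)
        w[idx] = ws
        obj = objective(w)
        if obj < best:
            best = obj
            best_support = frozenset(int(i) for i in idx)
    return best, best_support


def truncated_normal_pvalue_quadrature(x, vlo, vup, sd):
    """Two-sided truncated-Gaussian p-value by numerical integration (1e-10 tol)."""
    pdf = stats.norm(scale=sd).pdf
    hi = vup if np.isfinite(vup) else x + 40 * sd
    lo = vlo if np.isfinite(vlo) else x - 40 * sd
    den, _ = integrate.quad(pdf, lo, hi, epsabs=1e-14, epsrel=1e-12)
    num_low, _ = integrate.quad(pdf, lo, x, epsabs=1e-14, epsrel=1e-12)
    F = num_low / den
    return min(1.0, 2.0 * min(F, 1.0 - F))


def permutation_null_bruteforce(X_df, ys, fits, regulator, B, seed, chunk=100):
    """Gene-by-gene loop recomputation of the permutation null.

    Draws the identical permutation streams as
    :func:`regnet.targets.permutation_null` (same rng construction and order)
    but computes every error change with explicit per-gene, per-sample loops
    instead of vectorised algebra.
    """
    names = list(X_df.columns)
    arr = X_df.to_numpy(float)
    n = arr.shape[0]
    rng = np.random.default_rng(seed)
    total = np.zeros((B, n))
    for fit, y in zip(fits, ys):
        y = np.asarray(y, float)
        coef = fit.coefficients
        cols = [f for f in names if coef.get(f, 0.0) != 0.0]
        if regulator not in cols:
            cols.append(regulator)
        cols.sort(key=names.index)
        k = len(cols)
        w = [coef.get(f, 0.0) for f in cols]
        sub = arr[:, [names.index(f) for f in cols]]
        r_pos = cols.index(regulator)
        wr = coef.get(regulator, 0.0)
        done = 0
        while done < B:
            b = min(chunk, B - done)
            idx = np.argsort(rng.random((b, n, k)), axis=1)
            for bi in range(b):
                for g in range(n):
                    yhat = fit.intercept
                    for j in range(k):
                        yhat += w[j] * sub[idx[bi, g, j], j]
                    resid = y[g] - yhat
                    xr = sub[idx[bi, g, r_pos], r_pos]
                    total[done + bi, g] += (resid + wr * xr) ** 2 - resid ** 2
            done += b
    return total
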