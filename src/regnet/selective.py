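"""Post-selection (selective) inference for lasso-selected features.

Classical tests are invalid for coefficients chosen adaptively by the lasso.
At a fixed penalty the selection event {active set A with signs s} is a
polyhedron {y : Ay <= b} in response space, so conditionally on selection the
relaxed least-squares coefficient of an active feature, eta' y, follows a
Gaussian truncated to an interval [V-, V+] determined by the polyhedron
(the fixed-lambda polyhedral lemma).  Two-sided p-values come from the
truncated-Gaussian distribution, evaluated with log-space tail arithmetic so
that extreme truncations do not underflow.

Counting, per feature, the samples in which it is active *and* selectively
significant yields the ranked candidate-regulator table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr

from .lasso import RegressionFit, _as_array, _standardize, fit_lasso

__all__ = [
    "SelectiveTestResult",
    "selective_pvalues",
    "estimate_sigma",
    "count_selections",
    "rank_regulators",
]


def _log_interval_prob(a: float, b: float) -> float:
    """log P(a < Z < b) for a standard normal, stable in either tail."""
    if b <= a:
        return -np.inf
    if a > 0:  # both in upper tail: use survival functions
        la, lb = log_ndtr(-a), log_ndtr(-b)
        with np.errstate(divide="ignore"):
            return float(la + np.log1p(-np.exp(lb - la)))
    if b < 0:  # both in lower tail
        la, lb = log_ndtr(a), log_ndtr(b)
        with np.errstate(divide="ignore"):
            return float(lb + np.log1p(-np.exp(la - lb)))
    return float(np.log(ndtr(b) - ndtr(a)))


def _truncnorm_pvalue(x: float, vlo: float, vup: float, sd: float,
                      two_sided: bool = True) -> float:
    """p-value of x ~ N(0, sd^2) truncated to [vlo, vup], H0: mean 0.

    Returns 1.0 when the truncation interval is (numerically) degenerate.
    """
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("sd must be positive")
    a, b, u = vlo / sd, vup / sd, x / sd
    if not b > a:
        return 1.0
    u = min(max(u, a), b)
    log_den = _log_interval_prob(a, b)
    if log_den == -np.inf:
        return 1.0
    log_lower = _log_interval_prob(a, u)  # P(a < Z < u)
    log_upper = _log_interval_prob(u, b)  # P(u < Z < b)
    F = np.exp(log_lower - log_den) if log_lower > -np.inf else 0.0
    S = np.exp(log_upper - log_den) if log_upper > -np.inf else 0.0
    if two_sided:
        return float(min(1.0, 2.0 * min(F, S)))
    return float(min(1.0, S))


@dataclass
class SelectiveTestResult:
    """Selective p-values for the active features of one sample's fit."""

    lam: float
    active_features: list[tuple[str, int]]  # (name, sign)
    p_values: dict[str, float]
    sigma_hat: float
    sample: str | None = None
    coefficients: dict[str, float] = field(default_factory=dict)

    @property
    def active_names(self) -> list[str]:
        return [name for name, _ in self.active_features]


def selective_pvalues(
    X,
    y,
    lam: float,
    sigma: float,
    *,
    fit: RegressionFit | None = None,
    two_sided: bool = True,
    sample: str | None = None,
) -> SelectiveTestResult:
    """Fixed-lambda polyhedral inference for the lasso active set.

    Conditions on the active set and signs of the lasso solution at ``lam``
    (the solver's 1/(2n)-scaled penalty).  For each active feature the test
    statistic is the relaxed least-squares coefficient on the active design;
    its truncation interval is read off the selection polyhedron.  The design
    is standardised and the response centred exactly as in the fit, which
    leaves p-values invariant.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X, y, names = _as_array(X, y)
    n, p = X.shape
    if fit is None:
        fit = fit_lasso(X, y, lam, sample=sample)
    Xs, _, _ = _standardize(X, True)
    yc = y - y.mean()

    w = fit.coef_array() * fit.standardization[1]  # standardized-scale coefs
    active_idx = np.flatnonzero(w != 0.0)
    if active_idx.size == 0:
        return SelectiveTestResult(lam=float(lam), active_features=[],
                                   p_values={}, sigma_hat=float(sigma),
                                   sample=sample)
    if active_idx.size >= n:
        raise ValueError("active set must be smaller than the sample size")
    s = np.sign(w[active_idx])
    XA = Xs[:, active_idx]
    Xi = np.delete(Xs, active_idx, axis=1)
    lamL = lam * n  # penalty on the unscaled (1/2)||.||^2 objective

    GA_inv = np.linalg.pinv(XA.T @ XA)
    XA_pinv = GA_inv @ XA.T                       # (|A|, n)

    # selection polyhedron {A0;A1} yc <= {b0;b1}  (active set + signs)
    rows, offs = [], []
    if Xi.shape[1] > 0:
        R = (Xi.T - (Xi.T @ XA) @ XA_pinv) / lamL  # Xi' (I - P) without the n x n eye
        u = Xi.T @ (XA @ (GA_inv @ s))
        rows += [R, -R]
        offs += [1.0 - u, 1.0 + u]
    A1 = -(s[:, None] * XA_pinv)
    b1 = -lamL * (s * (GA_inv @ s))
    rows.append(A1)
    offs.append(b1)
    Amat = np.vstack(rows)
    bvec = np.concatenate(offs)

    pvals: dict[str, float] = {}
    active_pairs: list[tuple[str, int]] = []
    slack = bvec - Amat @ yc
    for row_k, j in enumerate(active_idx):
        eta = XA_pinv[row_k]
        eta_sq = float(eta @ eta)
        c = eta / eta_sq
        T = float(eta @ yc)
        rho = Amat @ c
        z_slack = slack + rho * T  # b - A z  with  z = yc - c*T
        eps = 1e-12 * max(1.0, float(np.max(np.abs(bvec))))
        neg = rho < -eps
        pos = rho > eps
        vlo = np.max((z_slack[neg]) / rho[neg]) if neg.any() else -np.inf
        vup = np.min((z_slack[pos]) / rho[pos]) if pos.any() else np.inf
        sd = sigma * np.sqrt(eta_sq)
        pvals[names[j]] = _truncnorm_pvalue(T, vlo, vup, sd, two_sided)
        active_pairs.append((names[j], int(np.sign(w[j]))))

    return SelectiveTestResult(
        lam=float(lam),
        active_features=active_pairs,
        p_values=pvals,
        sigma_hat=float(sigma),
        sample=sample,
        coefficients=dict(fit.coefficients),
    )


def estimate_sigma(X, y, active: list[str] | None = None) -> float:
    """Residual-SD noise estimate for selective inference.

    Uses degrees-of-freedom-corrected least squares on the full design when
    n > p + 1, otherwise on the supplied lasso-active columns.
    """
    X, y, names = _as_array(X, y)
    n, p = X.shape
    if np.allclose(y, y[0]):
        warnings.warn("constant response: sigma_hat = 0", stacklevel=2)
        return 0.0
    if n > p + 1:
        cols = np.arange(p)
    else:
        if not active:
            raise ValueError("n <= p requires a non-empty active set")
        idx = {f: j for j, f in enumerate(names)}
        cols = np.array([idx[f] for f in active])
        if n <= len(cols) + 1:
            raise ValueError("active set too large for a residual SD estimate")
    Z = np.column_stack([np.ones(n), X[:, cols]])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    rss = float(np.sum((y - Z @ beta) ** 2))
    dof = n - len(cols) - 1
    return float(np.sqrt(max(rss, 0.0) / dof))


def count_selections(
    results: list[SelectiveTestResult],
    alpha: float = 0.05,
    *,
    feature_names: list[str] | None = None,
    classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Table of how often each feature is active and selectively significant.

    ``n_selected`` counts samples where the feature is in the active set AND
    its selective p-value is below ``alpha``; ``selection_pct`` is the
    percentage over all samples.  Sorted by n_selected descending, ties by
    regulator name.
    """
    if not results:
        raise ValueError("need at least one per-sample result")
    n_samples = len(results)
    counts: dict[str, int] = {}
    if feature_names:
        counts.update({f: 0 for f in feature_names})
    for res in results:
        for name, p in res.p_values.items():
            counts.setdefault(name, 0)
            if p < alpha:
                counts[name] += 1
    table = pd.DataFrame(
        {
            "regulator": list(counts),
            "class": [(classes or {}).get(f, "") for f in counts],
            "n_selected": list(counts.values()),
        }
    )
    table["selection_pct"] = 100.0 * table["n_selected"] / n_samples
    table = table.sort_values(
        ["n_selected", "regulator"], ascending=[False, True]
    ).reset_index(drop=True)
    return table


def rank_regulators(table: pd.DataFrame, min_samples: int) -> pd.DataFrame:
    """Keep regulators selected in strictly more than ``min_samples`` samples."""
    out = table[table["n_selected"] > min_samples]
    return out.sort_values(["n_selected", "regulator"],
                           ascending=[False, True]).reset_index(drop=True)
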