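"""Target-gene discovery by leave-one-regulator-out error changes.

For a fitted per-sample model, "removing" a regulator r zeroes its fitted
contribution: yhat_without = yhat - w_r * x_r.  The per-gene change in squared
prediction error, summed across samples,

    D_g = sum_s [ (y_gs - yhat_gs + w_rs x_gr)^2 - (y_gs - yhat_gs)^2 ]

is large exactly for genes whose expression the regulator's sites help
explain.  Significance comes from a permutation null: every feature column is
shuffled independently (fresh permutations per replicate and per sample), the
original coefficients are re-applied to the shuffled design, and D_g is
recomputed; the empirical p-value is (1 + #{null >= observed}) / (B + 1),
one-sided because a target's error should *increase* on removal.  Targets are
the genes passing a Benjamini-Hochberg threshold applied per regulator across
genes.

Only columns entering the fitted prediction (nonzero coefficient, plus the
probed regulator) are actually shuffled: a permuted column multiplied by a
zero coefficient cannot change any prediction, so this is exactly equivalent
to shuffling the whole matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lasso import RegressionFit

__all__ = [
    "NullDistribution",
    "TargetCall",
    "delta_error",
    "summed_delta_error",
    "permutation_null",
    "empirical_pvalues",
    "call_targets",
    "discover_targets",
    "overlap_report",
    "ecdf_groups",
    "make_validation_groups",
]


def _columns(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"f{j}" for j in range(X.shape[1])]


def delta_error(fit: RegressionFit, X, y, regulator: str) -> np.ndarray:
    """Per-gene squared-error change when ``regulator`` is removed from the fit.

    Exactly zero for genes with no site for the regulator or when its fitted
    coefficient is zero.
    """
    arr, names = _columns(X)
    if regulator not in names:
        raise ValueError(f"regulator {regulator!r} not in feature matrix")
    y = np.asarray(y, dtype=float)
    resid = y - fit.predict(arr if not isinstance(X, pd.DataFrame) else X)
    wr = fit.coefficients.get(regulator, 0.0)
    xr = arr[:, names.index(regulator)]
    return (resid + wr * xr) ** 2 - resid ** 2


def summed_delta_error(fits: list[RegressionFit], X, ys, regulator: str) -> np.ndarray:
    """Element-wise sum of per-gene error changes across samples.

    ``X`` may be one shared feature matrix or a per-sample list.
    """
    Xs = X if isinstance(X, list) else [X] * len(fits)
    if not (len(fits) == len(Xs) == len(ys)):
        raise ValueError("fits, X and ys must align per sample")
    total = None
    for fit, Xi, yi in zip(fits, Xs, ys):
        d = delta_error(fit, Xi, yi, regulator)
        total = d if total is None else total + d
    return total


@dataclass
class NullDistribution:
    """Permutation replicates of the summed error change, per gene."""

    regulator: str
    B: int
    samples: np.ndarray  # (B, n_genes)
    genes: list[str]

    def __post_init__(self) -> None:
        if self.B < 1 or self.samples.shape != (self.B, len(self.genes)):
            raise ValueError("inconsistent null-distribution dimensions")


def permutation_null(
    X,
    ys: list[np.ndarray],
    fits: list[RegressionFit],
    regulator: str,
    B: int = 5000,
    seed: int = 0,
    *,
    chunk: int = 100,
    perm_fn=None,
) -> NullDistribution:
    """Null distribution of the summed error change under column shuffling.

    Each replicate shuffles the rows of every (prediction-relevant) feature
    column independently, per sample, and recomputes the summed removal error
    change using the original fitted coefficients (no refitting).  ``perm_fn``
    is a test hook: ``perm_fn(rng, B_chunk, n, k) -> (B_chunk, n, k)`` integer
    index array (defaults to independent uniform permutations).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    arr, names = _columns(X)
    if regulator not in names:
        raise ValueError(f"regulator {regulator!r} not in feature matrix")
    n = arr.shape[0]
    rng = np.random.default_rng(seed)
    genes = list(X.index) if isinstance(X, pd.DataFrame) else [str(i) for i in range(n)]

    if perm_fn is None:
        def perm_fn(rng, b, n, k):
            return np.argsort(rng.random((b, n, k)), axis=1)

    total = np.zeros((B, n))
    for fit, y in zip(fits, ys):
        y = np.asarray(y, dtype=float)
        coef = fit.coefficients
        # columns that can influence predictions, plus the probed regulator
        cols = [f for f in names if coef.get(f, 0.0) != 0.0]
        if regulator not in cols:
            cols.append(regulator)
        cols.sort(key=names.index)
        k = len(cols)
        w = np.array([coef.get(f, 0.0) for f in cols])
        sub = arr[:, [names.index(f) for f in cols]]
        r_pos = cols.index(regulator)
        wr = coef.get(regulator, 0.0)
        base = y - fit.intercept
        done = 0
        while done < B:
            b = min(chunk, B - done)
            idx = perm_fn(rng, b, n, k)
            Xp = np.take_along_axis(sub[None, :, :].repeat(b, axis=0), idx, axis=1)
            resid = base[None, :] - np.einsum("bnk,k->bn", Xp, w)
            xr = Xp[:, :, r_pos]
            total[done:done + b] += (resid + wr * xr) ** 2 - resid ** 2
            done += b
    return NullDistribution(regulator=regulator, B=B, samples=total, genes=genes)


def empirical_pvalues(observed: np.ndarray, null: NullDistribution) -> np.ndarray:
    """p = (1 + #{null >= observed}) / (B + 1), never zero, minimum 1/(B+1)."""
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (len(null.genes),):
        raise ValueError("observed vector does not match the null's gene list")
    exceed = (null.samples >= observed[None, :]).sum(axis=0)
    return (1.0 + exceed) / (null.B + 1.0)


@dataclass
class TargetCall:
    regulator: str
    gene: str
    delta_error: float
    p_emp: float
    q_value: float


def call_targets(
    pvalues: pd.Series,
    q_threshold: float = 2e-4,
    *,
    regulator: str = "",
    deltas: pd.Series | None = None,
) -> pd.DataFrame:
    """Benjamini-Hochberg across genes (per regulator); targets have q <= threshold.

    A target call is positive evidence that removing the regulator *increases*
    the gene's prediction error, so when the observed error changes are
    supplied a call additionally requires ``delta_error > 0`` (a gene with no
    site for the regulator has an identically-zero error change and can never
    be a target).  Returns the full per-gene table (p, q, called flag) sorted
    by q then gene.
    """
    p = pvalues.to_numpy(dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame({
        "regulator": regulator,
        "gene": pvalues.index,
        "delta_error": (deltas.reindex(pvalues.index).to_numpy()
                        if deltas is not None else np.nan),
        "p_emp": p,
        "q_value": q,
    })
    out["is_target"] = out["q_value"] <= q_threshold
    if deltas is not None:
        out["is_target"] &= out["delta_error"] > 0
    return out.sort_values(["q_value", "gene"]).reset_index(drop=True)


def discover_targets(
    X,
    ys: list[np.ndarray],
    fits: list[RegressionFit],
    regulator: str,
    B: int = 5000,
    seed: int = 0,
    q_threshold: float = 2e-4,
) -> pd.DataFrame:
    """observed summed error change -> permutation null -> empirical p -> BH calls."""
    observed = summed_delta_error(fits, X, ys, regulator)
    null = permutation_null(X, ys, fits, regulator, B=B, seed=seed)
    p = empirical_pvalues(observed, null)
    genes = null.genes
    return call_targets(pd.Series(p, index=genes), q_threshold,
                        regulator=regulator,
                        deltas=pd.Series(observed, index=genes))


def overlap_report(predicted: set, reference: set) -> dict:
    """Set overlap between predicted targets and a reference target set."""
    predicted, reference = set(predicted), set(reference)
    inter = predicted & reference
    if predicted:
        frac = len(inter) / len(predicted)
    else:
        warnings.warn("empty predicted set: overlap fraction reported as 0",
                      stacklevel=2)
        frac = 0.0
    return {
        "n_predicted": len(predicted),
        "n_reference": len(reference),
        "n_intersection": len(inter),
        "fraction_predicted_in_reference": frac,
    }


def make_validation_groups(
    all_genes: list[str],
    reference_targets: set,
    predicted_targets: set,
    motif_genes: set,
) -> dict[str, set]:
    """Disjoint gene groups for the LFC-ECDF comparison.

    (i) reference (e.g. CLIP-derived) targets, (ii) model-predicted targets
    not in (i), (iii) genes with at least one motif site but in neither (i)
    nor (ii), (iv) genes with no site.
    """
    universe = set(all_genes)
    ref = reference_targets & universe
    pred = (predicted_targets & universe) - ref
    motif = (motif_genes & universe) - ref - pred
    no_site = universe - motif_genes - ref - pred
    return {
        "reference_targets": ref,
        "predicted_targets": pred,
        "motif_only": motif,
        "no_site": no_site,
    }


def ecdf_groups(
    lfc: pd.Series, groups: dict[str, set]
) -> dict:
    """Per-group ECDFs on a pooled grid plus pairwise KS statistics.

    Groups must be disjoint; empty groups are skipped with a warning.
    """
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if set(groups[a]) & set(groups[b]):
                raise ValueError(f"groups {a!r} and {b!r} overlap")
    values: dict[str, np.ndarray] = {}
    for name in names:
        genes = [g for g in groups[name] if g in lfc.index]
        if not genes:
            warnings.warn(f"group {name!r} is empty; skipped", stacklevel=2)
            continue
        values[name] = lfc.loc[genes].to_numpy(dtype=float)
    grid = np.sort(np.concatenate(list(values.values()))) if values else np.array([])
    ecdfs = {name: np.searchsorted(np.sort(v), grid, side="right") / len(v)
             for name, v in values.items()}
    ks_rows = []
    kept = list(values)
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            res = stats.ks_2samp(values[a], values[b])
            ks_rows.append({"group_a": a, "group_b": b,
                            "ks_statistic": float(res.statistic),
                            "p_value": float(res.pvalue)})
    return {"grid": grid, "ecdf": ecdfs, "ks": pd.DataFrame(ks_rows),
            "group_sizes": {k: len(v) for k, v in values.items()}}
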