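"""Expression and methylation preprocessing.

RNA-seq "scaled estimate" abundances are converted to TPM (x 1e6), genes with
<= 0.1 TPM in more than 70% of samples are removed, and TPM is
log2-transformed (pseudocount 1, so zero stays zero).  For methylation, the
probe whose beta-value correlates most negatively (Pearson) with the gene's
expression across samples is selected, methylation being canonically
repressive.  miRNA count tables are filtered on counts-per-million over the
miRNA library size.  All filters are idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "to_tpm",
    "filter_low_expression",
    "log2_transform",
    "select_methylation_probe",
    "filter_low_mirna",
]

SCALES = ("scaled_estimate", "tpm", "log2tpm", "counts")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale tag."""

    values: pd.DataFrame
    scale: str = "log2tpm"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale in ("scaled_estimate", "tpm", "counts"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError(f"negative values on {self.scale} scale")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def _require_scale(em: ExpressionMatrix, scale: str) -> None:
    if em.scale != scale:
        raise ValueError(f"expected scale {scale!r}, got {em.scale!r}")


def to_tpm(em: ExpressionMatrix) -> ExpressionMatrix:
    """Scaled estimates x 1e6 -> transcripts per million."""
    _require_scale(em, "scaled_estimate")
    return ExpressionMatrix(em.values * 1e6, scale="tpm")


def filter_low_expression(em: ExpressionMatrix, tpm_floor: float = 0.1,
                          frac: float = 0.70) -> ExpressionMatrix:
    """Drop genes with TPM <= ``tpm_floor`` in more than ``frac`` of samples.

    The rule is strict ("more than"): a gene at the floor in exactly 70% of
    samples is kept.
    """
    _require_scale(em, "tpm")
    n = em.values.shape[1]
    n_low = (em.values <= tpm_floor).sum(axis=1)
    keep = n_low <= frac * n
    return ExpressionMatrix(em.values.loc[keep], scale="tpm")


def log2_transform(em: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """value -> log2(value + pseudocount); strictly monotone for pseudocount > 0."""
    _require_scale(em, "tpm")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (em.values.to_numpy() < 0).any():
        raise ValueError("negative TPM values")
    return ExpressionMatrix(np.log2(em.values + pseudocount), scale="log2tpm")


def select_methylation_probe(
    probe_betas: pd.DataFrame, expression: pd.Series
) -> tuple[str, pd.Series]:
    """Pick the probe with the strongest negative Pearson correlation to expression.

    ``probe_betas`` is probes x samples for one gene; samples must match the
    expression vector.  Zero-variance probes get r = 0 (they cannot win unless
    every probe is zero-variance).  Ties break on the probe identifier.  If
    even the best correlation is non-negative a warning is emitted.
    """
    if probe_betas.shape[0] < 1:
        raise ValueError("need at least one probe")
    if probe_betas.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation")
    expr = expression.loc[probe_betas.columns].to_numpy(dtype=float)
    if np.std(expr) == 0:
        warnings.warn("constant expression: correlations undefined, treated as 0",
                      stacklevel=2)
    rs: list[tuple[float, str]] = []
    all_flat = True
    for probe, row in probe_betas.iterrows():
        b = row.to_numpy(dtype=float)
        if np.std(b) == 0 or np.std(expr) == 0:
            r = 0.0
        else:
            all_flat = False
            r = float(np.corrcoef(b, expr)[0, 1])
        rs.append((r, str(probe)))
    if all_flat:
        chosen = min(p for _, p in rs)
    else:
        informative = [(r, p) for (r, p) in rs
                       if probe_betas.loc[p].std() > 0 and np.std(expr) > 0]
        chosen = min(informative)[1]
        if min(informative)[0] >= 0:
            warnings.warn("no negatively correlated probe; selecting the "
                          "least-positive correlation", stacklevel=2)
    return chosen, probe_betas.loc[chosen]


def filter_low_mirna(counts: pd.DataFrame, cpm_floor: float = 1.0,
                     frac: float = 0.70) -> pd.DataFrame:
    """Drop miRNAs below ``cpm_floor`` CPM in more than ``frac`` of samples.

    CPM is computed per sample over the total miRNA library size.  A zero
    library size is an error.
    """
    if counts.empty:
        return counts.copy()
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero miRNA library size in samples {bad[:5]}")
    cpm = counts / lib * 1e6
    n = counts.shape[1]
    n_low = (cpm < cpm_floor).sum(axis=1)
    return counts.loc[n_low <= frac * n].copy()
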