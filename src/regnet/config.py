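"""Configuration objects for simulations and pipeline runs.

A :class:`SimulationConfig` fixes the study conditions of a synthetic run:
how many genes and tumour samples, how many regulator features of each class
(TF, miRNA, RBP), how many of them truly drive expression, their effect
sizes, and the sparsity of the binding-site count columns.  The expression
model is

    y_g = w0 + wC*C_g + wM*M_g + sum_f w_f * N_gf + eps,   eps ~ N(0, noise_sd^2)

fitted once per sample; true weights are drawn once and jittered per sample
by a uniform factor so that per-sample fits see coherent but non-identical
effects.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

REGULATOR_CLASSES = ("TF", "MIRNA", "RBP")
COVARIATE_CLASSES = ("CNV", "METH")


class ConfigurationError(ValueError):
    """Raised when a configuration fails validation."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic-data generator.

    Defaults describe the desk-scale regulator-recovery condition: 2000 genes,
    40 tumour samples, 48 regulator features plus CNV and methylation, ten
    planted regulators with absolute effects in [0.5, 2.0] on log2-expression,
    and unit Gaussian noise.
    """

    n_genes: int = 2000
    n_samples: int = 40
    n_tf: int = 20
    n_mirna: int = 14
    n_rbp: int = 14
    #: planted (truly active) regulators per class, order (TF, MIRNA, RBP)
    n_active_per_class: tuple[int, int, int] = (4, 3, 3)
    #: (low, high) absolute effect size of planted regulator weights
    weight_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 1.0
    #: mean of the Poisson site-count distribution of regulator columns
    site_density: float = 0.5
    cnv_effect: float = 0.5
    meth_effect: float = -2.0
    intercept: float = 5.0
    #: per-sample multiplicative jitter applied to every true weight
    sample_weight_jitter: tuple[float, float] = (0.8, 1.2)
    #: mean LFC shift of planted targets in matched tumour/normal tables
    lfc_shift: float = 1.0
    lfc_noise_sd: float = 0.5
    # sequence-fixture geometry; regions must comfortably host the planted
    # sites (Poisson tails of every motif sharing the region) plus background
    promoter_flank: int = 200
    utr_length: int = 400
    tf_motif_width: int = 8
    mirna_seed_length: int = 7
    rbp_motif_width: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if min(self.n_genes, self.n_samples) <= 0:
            raise ConfigurationError("n_genes and n_samples must be positive")
        if min(self.n_tf, self.n_mirna, self.n_rbp) < 0:
            raise ConfigurationError("feature class sizes must be non-negative")
        n_act = self.n_active_per_class
        if len(n_act) != 3 or any(a < 0 for a in n_act):
            raise ConfigurationError("n_active_per_class must be three non-negative counts")
        for a, size in zip(n_act, (self.n_tf, self.n_mirna, self.n_rbp)):
            if a > size:
                raise ConfigurationError("n_active_per_class exceeds class size")
        lo, hi = self.weight_range
        if not (0 < lo <= hi):
            raise ConfigurationError("weight_range requires 0 < low <= high")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.site_density < 0:
            raise ConfigurationError("site_density must be >= 0")
        if self.promoter_flank <= 0 or self.utr_length <= 0:
            raise ConfigurationError("sequence regions must have positive length")

    @property
    def n_regulators(self) -> int:
        return self.n_tf + self.n_mirna + self.n_rbp

    @property
    def n_features(self) -> int:
        """Total feature count including the CNV and METH covariates."""
        return self.n_regulators + 2

    @property
    def nonzero_rate(self) -> float:
        """Probability that a regulator has >= 1 site in a gene."""
        return float(1.0 - np.exp(-self.site_density))

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        for key in ("n_active_per_class", "weight_range", "sample_weight_jitter"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration (thresholds mirror the analysis defaults)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str | None = None
    # preprocessing thresholds
    tpm_floor: float = 0.1
    low_frac: float = 0.70
    pseudocount: float = 1.0
    # feature building
    fimo_p: float = 1e-4
    top_kmers: int = 10
    # model fitting / selection
    folds: int = 10
    alpha: float = 0.05
    min_samples: int | None = None  # None -> 15% of samples, rounded
    # target discovery
    permutations: int = 5000
    q_threshold: float = 2e-4
    max_target_regulators: int = 5
    # stage toggles
    stages: tuple[str, ...] = (
        "simulate",
        "build_features",
        "fit",
        "select",
        "targets",
        "validate",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.low_frac < 1):
            raise ConfigurationError("low_frac must be in (0, 1)")
        if not (0 < self.fimo_p <= 1):
            raise ConfigurationError("fimo_p must be in (0, 1]")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if not (0 < self.alpha <= 1) or not (0 < self.q_threshold <= 1):
            raise ConfigurationError("alpha and q_threshold must be in (0, 1]")
        if self.permutations < 1:
            raise ConfigurationError("permutations must be >= 1")
        unknown = set(self.stages) - {
            "simulate", "build_features", "preprocess", "fit", "select",
            "targets", "validate",
        }
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    def resolved_min_samples(self) -> int:
        if self.min_samples is not None:
            return self.min_samples
        return max(2, int(round(0.15 * self.simulation.n_samples)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig.from_dict(raw.pop("simulation", {}) or {})
        if "stages" in raw and raw["stages"] is not None:
            raw["stages"] = tuple(raw["stages"])
        return cls(simulation=sim, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def stable_seed(master_seed: int, *key: Any) -> int:
    """Deterministic 31-bit child seed keyed by strings/ints."""
    h = hashlib.blake2s(repr(("regnet", master_seed) + key).encode(), digest_size=4)
    return int.from_bytes(h.digest(), "little") % (2**31)


def child_rng(master_seed: int, *key: Any) -> np.random.Generator:
    """Deterministic per-stage generator keyed by strings/ints.

    Hashing the key into the seed sequence keeps independent stages
    independent without threading generator state through the pipeline.
    A stable digest is used (Python's built-in ``hash`` is salted per process).
    """
    h = hashlib.blake2s(repr(("regnet",) + key).encode(), digest_size=4)
    digest = int.from_bytes(h.digest(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence((master_seed, digest)))
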