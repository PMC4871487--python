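"""Synthetic data with planted regulators, targets, motifs and sequences.

The generator emulates the statistical structure the analysis assumes:

* sparse non-negative binding-site count columns (Poisson counts, so a gene
  carries a site with probability 1 - exp(-site_density));
* a GISTIC-like CNV covariate (discrete levels -2..2 plus jitter) and a
  Beta(2,2) methylation covariate entering with a negative weight by default;
* expression built by the linear model y = w0 + wC*C + wM*M + sum w*N + eps,
  with true weights drawn once and jittered per sample by U(0.8, 1.2) so
  per-sample fits see coherent effects;
* matched tumour/normal log-fold-change tables in which the planted targets
  of a chosen regulator are shifted;
* FASTA sequences, annotations, JASPAR-style PFMs and peak intervals whose
  motif content reproduces the count matrix *exactly*: each region is
  rejection-sampled against the same counting functions the feature builder
  uses, so the round trip sequences -> counts is an identity by construction.

Every generator is a pure function of (config, seed): seeded reruns are
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import REGULATOR_CLASSES, SimulationConfig, ConfigurationError, child_rng
from .features import (
    ALPHABET,
    FeatureMatrix,
    GenomicInterval,
    PFM,
    assemble_feature_matrix,
    count_tf_sites,
    count_utr_kmer_sites,
    promoter_region,
    top_kmers,
)
from .preprocess import ExpressionMatrix

__all__ = [
    "SyntheticTruth",
    "SequenceBundle",
    "generate_features",
    "draw_truth",
    "generate_expression",
    "generate_matched_lfc",
    "generate_sequences",
]

_GISTIC_LEVELS = np.array([-2, -1, 0, 1, 2])
_GISTIC_PROBS = np.array([0.05, 0.20, 0.50, 0.20, 0.05])


@dataclass
class SyntheticTruth:
    """Planted ground truth: active regulators, per-sample weights, target sets."""

    active_regulators: set[str]
    #: sample -> feature -> true effect (includes CNV/METH and the intercept key "w0")
    weights: dict[str, dict[str, float]]
    #: regulator -> genes with a site for it (its true targets)
    target_sets: dict[str, set[str]]
    intercept: float

    def validate(self, features: FeatureMatrix) -> None:
        for reg, genes in self.target_sets.items():
            if reg not in self.active_regulators:
                raise ValueError(f"{reg} has targets but is not active")
            col = features.values[reg]
            if not all(col.loc[g] > 0 for g in genes):
                raise ValueError(f"target of {reg} without a binding site")

    def to_json(self, path) -> None:
        payload = {
            "active_regulators": sorted(self.active_regulators),
            "weights": {s: dict(sorted(w.items()))
                        for s, w in sorted(self.weights.items())},
            "target_sets": {r: sorted(g) for r, g in sorted(self.target_sets.items())},
            "intercept": self.intercept,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            active_regulators=set(d["active_regulators"]),
            weights={s: dict(w) for s, w in d["weights"].items()},
            target_sets={r: set(g) for r, g in d["target_sets"].items()},
            intercept=d["intercept"],
        )


def _feature_names(config: SimulationConfig) -> dict[str, list[str]]:
    return {
        "TF": [f"TF_{i+1:03d}" for i in range(config.n_tf)],
        "MIRNA": [f"miR_{i+1:03d}" for i in range(config.n_mirna)],
        "RBP": [f"RBP_{i+1:03d}" for i in range(config.n_rbp)],
    }


def generate_features(config: SimulationConfig) -> FeatureMatrix:
    """Gene x feature matrix: CNV, METH plus Poisson site-count columns."""
    config.validate()
    rng = child_rng(config.seed, "features")
    genes = [f"g{i+1:05d}" for i in range(config.n_genes)]
    names = _feature_names(config)

    cnv_levels = rng.choice(_GISTIC_LEVELS, size=config.n_genes, p=_GISTIC_PROBS)
    cnv = pd.Series(cnv_levels + rng.normal(0, 0.1, config.n_genes),
                    index=genes, name="CNV")
    meth = pd.Series(rng.beta(2.0, 2.0, config.n_genes), index=genes, name="METH")

    counts = {}
    for cls in REGULATOR_CLASSES:
        cols = names[cls]
        mat = rng.poisson(config.site_density, size=(config.n_genes, len(cols)))
        counts[cls] = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                                   columns=cols)
    blocks = [pd.DataFrame({"CNV": cnv, "METH": meth})]
    classes = {"CNV": "CNV", "METH": "METH"}
    for cls in REGULATOR_CLASSES:
        blocks.append(counts[cls].astype(float))
        classes.update({c: cls for c in counts[cls].columns})
    values = pd.concat(blocks, axis=1)
    values.index.name = "gene"
    return FeatureMatrix(values=values, classes=classes)


def draw_truth(features: FeatureMatrix, config: SimulationConfig) -> SyntheticTruth:
    """Plant active regulators and draw per-sample weights.

    Base effects are drawn once, |w| ~ U(weight_range) with random sign, then
    multiplied per sample by U(sample_weight_jitter), so every active
    regulator keeps its sign and rough magnitude across samples.
    """
    rng = child_rng(config.seed, "truth")
    names = _feature_names(config)
    lo, hi = config.weight_range
    jlo, jhi = config.sample_weight_jitter

    active: list[str] = []
    for cls, n_act in zip(REGULATOR_CLASSES, config.n_active_per_class):
        pool = [f for f in names[cls] if f in features.values.columns]
        if n_act > len(pool):
            raise ConfigurationError(f"not enough {cls} features to plant {n_act}")
        chosen = rng.choice(pool, size=n_act, replace=False)
        active.extend(sorted(chosen))

    base = {"CNV": config.cnv_effect, "METH": config.meth_effect}
    for reg in active:
        base[reg] = float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))

    samples = [f"S{i+1:03d}" for i in range(config.n_samples)]
    weights: dict[str, dict[str, float]] = {}
    for s in samples:
        jitter = {f: float(rng.uniform(jlo, jhi)) for f in base}
        weights[s] = {f: base[f] * jitter[f] for f in base}
        weights[s]["w0"] = config.intercept

    target_sets = {
        reg: set(features.values.index[features.values[reg] > 0])
        for reg in active
    }
    truth = SyntheticTruth(
        active_regulators=set(active),
        weights=weights,
        target_sets=target_sets,
        intercept=config.intercept,
    )
    truth.validate(features)
    return truth


def generate_expression(features: FeatureMatrix, truth: SyntheticTruth,
                        config: SimulationConfig) -> ExpressionMatrix:
    """Expression per sample from the linear model plus Gaussian noise."""
    rng = child_rng(config.seed, "expression")
    samples = sorted(truth.weights)
    if len(samples) != config.n_samples:
        raise ValueError("truth weights do not cover all samples")
    X = features.values
    cols = {}
    for s in samples:
        w = truth.weights[s]
        y = np.full(len(X), w.get("w0", truth.intercept), dtype=float)
        for feat, wf in w.items():
            if feat == "w0":
                continue
            if feat not in X.columns:
                raise ValueError(f"weighted feature {feat!r} missing from matrix")
            y += wf * X[feat].to_numpy()
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, len(X))
        cols[s] = y
    values = pd.DataFrame(cols, index=X.index)
    return ExpressionMatrix(values=values, scale="log2tpm")


def generate_matched_lfc(
    truth: SyntheticTruth,
    genes: list[str],
    config: SimulationConfig,
    regulator: str | None = None,
    *,
    shift: float | None = None,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-gene tumour/normal log fold changes with shifted planted targets.

    Targets of the chosen (by default the first active) regulator receive a
    mean shift of ``shift`` (positive for an up-regulated, stabilising
    regulator); non-targets are centred at zero.
    """
    rng = child_rng(config.seed if seed is None else seed, "lfc")
    if regulator is None:
        if not truth.active_regulators:
            raise ValueError("no active regulators in truth")
        regulator = sorted(truth.active_regulators)[0]
    if regulator not in truth.target_sets:
        raise ValueError(f"{regulator!r} has no target set")
    shift = config.lfc_shift if shift is None else shift
    noise_sd = config.lfc_noise_sd if noise_sd is None else noise_sd
    lfc = rng.normal(0.0, noise_sd, len(genes))
    targets = truth.target_sets[regulator]
    is_target = np.array([g in targets for g in genes])
    lfc = lfc + shift * is_target
    return pd.DataFrame({"gene": genes, "lfc": lfc,
                         "is_target": is_target}).set_index("gene")


# ---------------------------------------------------------------------------
# sequence fixtures
# ---------------------------------------------------------------------------


@dataclass
class SequenceBundle:
    """Sequences, annotations, motifs and peaks consistent with a count matrix."""

    sequences: dict[str, str]
    annotations: pd.DataFrame
    pfms: dict[str, list[PFM]]
    dnase_peaks: list[GenomicInterval]
    clip_peaks: list[GenomicInterval]
    background_peaks: list[GenomicInterval] = field(default_factory=list)
    fimo_p: float = 1e-4
    rbp_top_kmers: int = 10
    mirna_top_kmers: int = 1
    promoter_flank: int = 2000


def _draw_consensus(rng: np.random.Generator, width: int,
                    taken: set[str]) -> str:
    """Random non-palindromic consensus distinct from previously drawn ones."""
    from .features import reverse_complement

    for _ in range(1000):
        kmer = "".join(rng.choice(list(ALPHABET), size=width))
        if kmer in taken or reverse_complement(kmer) == kmer:
            continue
        return kmer
    raise RuntimeError("could not draw a fresh consensus k-mer")


def _place_sites(rng: np.random.Generator, length: int,
                 sites: list[str]) -> list[tuple[int, str]] | None:
    """Non-overlapping random placements for the given site strings."""
    placed: list[tuple[int, str]] = []
    occupied: list[tuple[int, int]] = []
    for s in sites:
        w = len(s)
        ok = False
        for _ in range(200):
            start = int(rng.integers(0, length - w + 1))
            if all(start + w <= a or start >= b for a, b in occupied):
                occupied.append((start, start + w))
                placed.append((start, s))
                ok = True
                break
        if not ok:
            return None
    return placed


def _fill_region(rng: np.random.Generator, length: int,
                 placements: list[tuple[int, str]]) -> str:
    seq = rng.choice(list(ALPHABET), size=length)
    for start, s in placements:
        seq[start:start + len(s)] = list(s)
    return "".join(seq)


def generate_sequences(features: FeatureMatrix, config: SimulationConfig,
                       *, max_rejects: int = 300) -> SequenceBundle:
    """Emit sequences whose builder-derived counts equal the feature matrix.

    One synthetic chromosome per gene carries a promoter (2 x flank around the
    TSS) hosting the TF sites and a 3'UTR hosting the miRNA/RBP sites.  Each
    region is re-sampled until the exact counting functions of the feature
    builder reproduce the planted counts, which excludes spurious background
    matches (and spurious cross-motif matches) outright.
    """
    rng = child_rng(config.seed, "sequences")
    names = _feature_names(config)
    widths = {"TF": config.tf_motif_width, "MIRNA": config.mirna_seed_length,
              "RBP": config.rbp_motif_width}
    taken: set[str] = set()
    pfms: dict[str, list[PFM]] = {}
    consensus: dict[str, str] = {}
    for cls in REGULATOR_CLASSES:
        pfms[cls] = []
        for name in names[cls]:
            if name not in features.values.columns:
                continue
            kmer = _draw_consensus(rng, widths[cls], taken)
            taken.add(kmer)
            consensus[name] = kmer
            pfms[cls].append(PFM.from_consensus(name, kmer))

    fimo_p = 1e-4
    rbp_top = 10
    mirna_top = 1
    top_kmer_cache = {
        pfm.name: top_kmers(pfm, rbp_top if cls == "RBP" else mirna_top)
        for cls in ("MIRNA", "RBP") for pfm in pfms[cls]
    }

    flank = config.promoter_flank
    utr_len = config.utr_length
    prom_len = 2 * flank
    spacer = 10

    sequences: dict[str, str] = {}
    annot_rows = []
    dnase, clip = [], []
    counts = features.values

    for gene in counts.index:
        chrom = f"chr_{gene}"
        tf_sites = []
        for pfm in pfms["TF"]:
            tf_sites += [consensus[pfm.name]] * int(counts.loc[gene, pfm.name])
        utr_sites = []
        for cls in ("MIRNA", "RBP"):
            for pfm in pfms[cls]:
                utr_sites += [consensus[pfm.name]] * int(counts.loc[gene, pfm.name])
        if sum(len(s) for s in tf_sites) > prom_len:
            raise ValueError(f"promoter of {gene} cannot host {len(tf_sites)} sites")
        if sum(len(s) for s in utr_sites) > utr_len:
            raise ValueError(f"3'UTR of {gene} cannot host {len(utr_sites)} sites")

        prom = _reject_sample_region(
            rng, prom_len, tf_sites, max_rejects,
            lambda seq: all(
                count_tf_sites(seq, pfm, fimo_p) == counts.loc[gene, pfm.name]
                for pfm in pfms["TF"]),
            gene, "promoter")
        utr = _reject_sample_region(
            rng, utr_len, utr_sites, max_rejects,
            lambda seq: all(
                count_utr_kmer_sites(seq, top_kmer_cache[pfm.name])
                == counts.loc[gene, pfm.name]
                for cls in ("MIRNA", "RBP") for pfm in pfms[cls]),
            gene, "3'UTR")

        seq = prom + "".join(rng.choice(list(ALPHABET), size=spacer)) + utr
        sequences[chrom] = seq
        utr_start = prom_len + spacer
        annot_rows.append({"gene": gene, "chrom": chrom, "tss": flank,
                           "strand": "+", "utr_start": utr_start,
                           "utr_end": utr_start + utr_len})
        dnase.append(GenomicInterval(chrom, 0, prom_len))
        clip.append(GenomicInterval(chrom, utr_start, utr_start + utr_len))

    return SequenceBundle(
        sequences=sequences,
        annotations=pd.DataFrame(annot_rows),
        pfms=pfms,
        dnase_peaks=dnase,
        clip_peaks=clip,
        fimo_p=fimo_p,
        rbp_top_kmers=rbp_top,
        mirna_top_kmers=mirna_top,
        promoter_flank=flank,
    )


def _reject_sample_region(rng, length, sites, max_rejects, predicate, gene, label):
    for _ in range(max_rejects):
        placements = _place_sites(rng, length, sites)
        if placements is None:
            continue
        seq = _fill_region(rng, length, placements)
        if predicate(seq):
            return seq
    raise RuntimeError(
        f"could not generate a {label} for {gene} matching its planted counts "
        f"({len(sites)} sites in {length} bp); the packing may be impossible")
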