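"""Binding-site featurization: motifs, intervals and the gene x feature matrix.

Feature columns are per-gene binding-site counts for three regulator classes:

* TF    — log-odds PFM scan of the +/-2 kb promoter around the TSS (both
          strands), keeping matches whose *exact* score p-value under a
          0-order background is below a threshold (default 1e-4), optionally
          restricted to open-chromatin (DNase) intervals;
* MIRNA — exact seed k-mer matches in the 3'UTR (single strand);
* RBP   — exact matches of the top-n highest-probability k-mers of an RBP
          PFM in the 3'UTR, optionally restricted to CLIP peaks after
          subtracting background-binding intervals.

Exact motif p-values are computed by dynamic programming over the
discretised log-odds score distribution of random k-mers under the
background (the standard construction used by motif scanners); the same
integerised scores are used for scoring windows, so scan decisions and DP
p-values are mutually consistent.

Covariate columns are GISTIC-style CNV levels and methylation beta-values.
Assembly intersects all sources on gene identifiers, removes regulators with
no site in any retained gene, and (as a separate, idempotent step) merges
features with identical count vectors into one column.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .config import COVARIATE_CLASSES, REGULATOR_CLASSES

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(ALPHABET):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

__all__ = [
    "PFM",
    "GenomicInterval",
    "MotifHit",
    "FeatureMatrix",
    "promoter_region",
    "scan_pfm",
    "top_kmers",
    "count_kmer_sites",
    "intersect_with_peaks",
    "assemble_feature_matrix",
    "merge_identical_features",
    "reverse_complement",
    "build_feature_counts",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval (BED convention)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


def promoter_region(tss: int, strand: str = "+", flank: int = 2000,
                    chrom: str = ".") -> GenomicInterval:
    """Promoter = [tss - flank, tss + flank), clipped at the chromosome start.

    The extent is strand-independent (a symmetric window around the TSS).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if tss < 0:
        raise ValueError("tss must be >= 0")
    return GenomicInterval(chrom, max(0, tss - flank), tss + flank, strand)


class PFM:
    """Position frequency matrix over A,C,G,T with a log-odds scanner.

    ``probs`` has one row per motif position; rows are renormalised to sum to
    one after adding ``pseudocount`` (which also keeps log-odds finite).
    """

    def __init__(self, name: str, probs: np.ndarray, pseudocount: float = 1e-4):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("PFM must be width x 4")
        if (probs < 0).any():
            raise ValueError("PFM probabilities must be non-negative")
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        self.name = name
        self.pseudocount = float(pseudocount)
        p = probs + pseudocount
        self.probs = p / p.sum(axis=1, keepdims=True)
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PFM rows failed to normalise")
        self._tables: dict = {}

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray,
                    pseudocount: float = 1e-4) -> "PFM":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum(axis=1, keepdims=True)
        if (total <= 0).any():
            raise ValueError("PFM count rows must be positive")
        return cls(name, counts / total, pseudocount=pseudocount)

    @classmethod
    def from_consensus(cls, name: str, consensus: str,
                       match_prob: float = 0.91) -> "PFM":
        """Near-deterministic PFM putting ``match_prob`` on each consensus base."""
        off = (1.0 - match_prob) / 3.0
        probs = np.full((len(consensus), 4), off)
        for i, b in enumerate(consensus.upper()):
            probs[i, ALPHABET.index(b)] = match_prob
        return cls(name, probs)

    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PFM":
        return PFM(self.name, self.probs[::-1, ::-1], pseudocount=self.pseudocount)

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        return np.log2(self.probs) - np.log2(background)[None, :]

    def score_table(self, background: np.ndarray | None = None,
                    n_bins: int = 1000) -> "_ScoreTable":
        bg = _check_background(background)
        key = (tuple(np.round(bg, 12)), n_bins)
        if key not in self._tables:
            self._tables[key] = _ScoreTable(self, bg, n_bins)
        return self._tables[key]


def _check_background(background) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 positive frequencies summing to 1")
    return bg


class _ScoreTable:
    """Integerised log-odds scores and the exact tail distribution.

    Scores are binned at (range / n_bins) resolution; the DP convolves the
    per-position integer score distributions under the background, giving the
    exact null distribution of the integerised score of a random k-mer.
    """

    def __init__(self, pfm: PFM, background: np.ndarray, n_bins: int = 1000):
        lo = pfm.log_odds(background)
        rng_span = float(lo.max(axis=1).sum() - lo.min(axis=1).sum())
        self.bin_width = rng_span / n_bins if rng_span > 0 else 1.0
        self.int_scores = np.round(lo / self.bin_width).astype(np.int64)
        self.float_scores = lo
        self.background = background
        self._build_tail()

    def _build_tail(self) -> None:
        mins = self.int_scores.min(axis=1)
        maxs = self.int_scores.max(axis=1)
        size = int((maxs - mins).sum()) + 1
        dist = np.zeros(size)
        dist[0] = 1.0
        upto = 0
        for i in range(self.int_scores.shape[0]):
            new = np.zeros(size)
            row = self.int_scores[i] - mins[i]
            for b in range(4):
                sh = int(row[b])
                new[sh:upto + sh + 1] += self.background[b] * dist[:upto + 1]
            dist = new
            upto += int(maxs[i] - mins[i])
        self.offset = int(mins.sum())
        # tail[k] = P(score_int >= k + offset)
        self.tail = np.cumsum(dist[::-1])[::-1]

    def pvalue_of_int(self, s: np.ndarray | int) -> np.ndarray:
        idx = np.atleast_1d(np.asarray(s, dtype=np.int64)) - self.offset
        idx = np.clip(idx, 0, len(self.tail) - 1)
        out = self.tail[idx]
        return np.where(np.atleast_1d(s) - self.offset < 0, 1.0, out)

    def window_scores(self, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(int scores, float scores, validity mask) for every window."""
        w = self.int_scores.shape[0]
        n_win = len(enc) - w + 1
        if n_win <= 0:
            return (np.empty(0, np.int64), np.empty(0), np.empty(0, bool))
        ints = np.zeros(n_win, dtype=np.int64)
        floats = np.zeros(n_win)
        valid = np.ones(n_win, dtype=bool)
        safe = np.where(enc < 0, 0, enc)
        for i in range(w):
            sl = safe[i:i + n_win]
            ints += self.int_scores[i][sl]
            floats += self.float_scores[i][sl]
            valid &= enc[i:i + n_win] >= 0
        return ints, floats, valid


@dataclass(frozen=True)
class MotifHit:
    offset: int
    strand: str
    score: float
    p_value: float


def scan_pfm(
    sequence: str,
    pfm: PFM,
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
    *,
    both_strands: bool = False,
    n_bins: int = 1000,
) -> list[MotifHit]:
    """Report motif matches whose exact score p-value is below ``p_threshold``.

    DNA (promoter) scanning uses ``both_strands=True``; RNA-side scanning of
    3'UTRs is single-stranded.  Overlapping hits are all reported; offsets are
    forward-strand coordinates of the window start.  Windows containing
    non-ACGT characters are skipped (logged once per scan).  A threshold >= 1
    is vacuous: every valid window is reported.
    """
    if len(sequence) == 0:
        return []
    if len(sequence) < pfm.width:
        return []
    bg = _check_background(background)
    enc = _encode(sequence)
    if (enc < 0).any():
        logger.warning("sequence contains %d non-ACGT characters; windows "
                       "covering them are skipped", int((enc < 0).sum()))
    hits: list[MotifHit] = []
    strands = [("+", pfm)]
    if both_strands:
        strands.append(("-", pfm.reverse_complement()))
    for strand, mat in strands:
        table = mat.score_table(bg, n_bins)
        ints, floats, valid = table.window_scores(enc)
        pvals = table.pvalue_of_int(ints)
        take = valid if p_threshold >= 1.0 else (valid & (pvals < p_threshold))
        for off in np.flatnonzero(take):
            hits.append(MotifHit(int(off), strand, float(floats[off]),
                                 float(pvals[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def top_kmers(pfm: PFM, n: int = 10) -> list[str]:
    """The n k-mers with the highest PFM probability, ties broken lexicographically.

    Best-first search over prefixes with an admissible bound (max attainable
    completion probability), so only the needed part of the 4^k space is
    expanded.  If n exceeds 4^k the full ranked k-mer list is returned.
    """
    if pfm.width > 12:
        raise ValueError("top_kmers enumeration is bounded at width 12")
    if n < 1:
        raise ValueError("n must be >= 1")
    logp = np.log(pfm.probs)
    w = pfm.width
    # bound[i] = max attainable log-prob of positions i..w-1
    bound = np.zeros(w + 1)
    for i in range(w - 1, -1, -1):
        bound[i] = bound[i + 1] + logp[i].max()
    heap: list[tuple[float, str]] = [(-bound[0], "")]
    out: list[str] = []
    limit = min(n, 4 ** w)
    while heap and len(out) < limit:
        neg, prefix = heapq.heappop(heap)
        i = len(prefix)
        if i == w:
            out.append(prefix)
            continue
        base_score = -neg - bound[i]  # exact log-prob of prefix
        for b, ch in enumerate(ALPHABET):
            sc = base_score + logp[i, b] + bound[i + 1]
            heapq.heappush(heap, (-sc, prefix + ch))
    return out


def _kmer_match_positions(seq: str, kmers: list[str]) -> set[int]:
    """Start positions (overlaps included) where any listed k-mer matches."""
    positions: set[int] = set()
    for k in kmers:
        start = seq.find(k)
        while start != -1:
            positions.add(start)
            start = seq.find(k, start + 1)
    return positions


def count_kmer_sites(sequence: str, kmers: list[str]) -> int:
    """Positions where any listed k-mer matches exactly (overlaps counted,
    a position counted once even if several k-mers match there)."""
    if not kmers:
        return 0
    return len(_kmer_match_positions(sequence.upper(),
                                     [k.upper() for k in kmers]))


def _effective_peak_tree(peaks, background):
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    for tree in trees.values():
        tree.merge_overlaps()
    for b in background or []:
        if b.chrom in trees:
            trees[b.chrom].chop(b.start, b.end)
    return trees


def intersect_with_peaks(
    hits: list[GenomicInterval],
    peaks: list[GenomicInterval] | None,
    background_regions: list[GenomicInterval] | None = None,
    *,
    no_peak_mode: str = "pass",
) -> list[GenomicInterval]:
    """Keep hits overlapping (>= 1 bp) the set difference peaks \\ background.

    With no peaks supplied the behaviour is a mode contract: ``"pass"``
    returns all hits (motif-only mode), ``"drop"`` returns none
    (peak-required mode).
    """
    if no_peak_mode not in {"pass", "drop"}:
        raise ValueError("no_peak_mode must be 'pass' or 'drop'")
    if not peaks:
        return list(hits) if no_peak_mode == "pass" else []
    trees = _effective_peak_tree(peaks, background_regions)
    kept = []
    for h in hits:
        tree = trees.get(h.chrom)
        if tree is not None and tree.overlap(h.start, h.end):
            kept.append(h)
    return kept


@dataclass
class FeatureMatrix:
    """Genes x features table with per-feature class labels.

    Regulator-class columns hold non-negative integer site counts; CNV and
    METH columns are real-valued covariates.  ``merged_members`` records the
    original features collapsed into each column by
    :func:`merge_identical_features`.
    """

    values: pd.DataFrame
    classes: dict[str, str]
    merged_members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.classes]
        if missing:
            raise ValueError(f"features without class label: {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def columns_of_class(self, cls: str) -> list[str]:
        return [f for f in self.values.columns if self.classes[f] == cls]

    @property
    def regulators(self) -> list[str]:
        return [f for f in self.values.columns
                if self.classes[f] in REGULATOR_CLASSES]

    def members_of(self, feature: str) -> list[str]:
        return self.merged_members.get(feature, [feature])


def assemble_feature_matrix(
    class_counts: dict[str, pd.DataFrame],
    cnv: pd.Series,
    meth: pd.Series,
    genes: list[str] | None = None,
) -> FeatureMatrix:
    """Intersect count/CNV/methylation sources on genes and stack the matrix.

    Genes absent from any source are dropped; regulator columns with no site
    in any retained gene are removed.  Raises on an empty gene intersection.
    """
    unknown = set(class_counts) - set(REGULATOR_CLASSES)
    if unknown:
        raise ValueError(f"unknown regulator classes: {sorted(unknown)}")
    sources: list[pd.Index] = [df.index for df in class_counts.values()]
    sources += [cnv.index, meth.index]
    if genes is not None:
        order = list(genes)
    else:
        order = list(sources[0])
    common = set(order)
    for idx in sources:
        common &= set(idx)
    kept = [g for g in order if g in common]
    if not kept:
        raise ValueError("empty gene intersection across feature sources")

    blocks = [pd.DataFrame({"CNV": cnv.loc[kept].astype(float),
                            "METH": meth.loc[kept].astype(float)})]
    classes: dict[str, str] = {"CNV": "CNV", "METH": "METH"}
    for cls in REGULATOR_CLASSES:
        if cls not in class_counts:
            continue
        block = class_counts[cls].loc[kept]
        if (block.to_numpy() < 0).any():
            raise ValueError(f"negative site counts in class {cls}")
        nonzero = block.columns[(block != 0).any(axis=0)]
        block = block[nonzero].astype(float)
        blocks.append(block)
        classes.update({f: cls for f in block.columns})
    values = pd.concat(blocks, axis=1)
    values.index.name = "gene"
    return FeatureMatrix(values=values, classes=classes)


def merge_identical_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Collapse exact-duplicate feature columns into single features.

    The representative is the first member in column order; its
    ``merged_members`` lists every original (members of members included, so
    the operation is idempotent).  The multiset of distinct columns is
    unchanged.
    """
    groups: dict[bytes, list[str]] = {}
    order: list[bytes] = []
    arr = fm.values.to_numpy()
    for k, col in enumerate(fm.values.columns):
        key = arr[:, k].tobytes()
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(col)
    keep_cols, members_map = [], {}
    for key in order:
        members = groups[key]
        rep = members[0]
        keep_cols.append(rep)
        all_members: list[str] = []
        for m in members:
            all_members.extend(fm.members_of(m))
        members_map[rep] = all_members
    values = fm.values[keep_cols].copy()
    classes = {f: fm.classes[f] for f in keep_cols}
    return FeatureMatrix(values=values, classes=classes,
                         merged_members=members_map)


# ---------------------------------------------------------------------------
# sequence-level counting used by the builder CLI and the synthetic round trip
# ---------------------------------------------------------------------------

def count_tf_sites(
    promoter_seq: str,
    pfm: PFM,
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
    *,
    chrom: str = ".",
    region_start: int = 0,
    dnase_peaks: list[GenomicInterval] | None = None,
    no_peak_mode: str = "pass",
) -> int:
    """TF site count: double-strand PFM scan filtered by open-chromatin peaks."""
    hits = scan_pfm(promoter_seq, pfm, p_threshold, background,
                    both_strands=True)
    intervals = [GenomicInterval(chrom, region_start + h.offset,
                                 region_start + h.offset + pfm.width, h.strand)
                 for h in hits]
    kept = intersect_with_peaks(intervals, dnase_peaks,
                                no_peak_mode=no_peak_mode)
    return len(kept)


def count_utr_kmer_sites(
    utr_seq: str,
    kmers: list[str],
    *,
    chrom: str = ".",
    region_start: int = 0,
    peaks: list[GenomicInterval] | None = None,
    background_regions: list[GenomicInterval] | None = None,
    no_peak_mode: str = "pass",
) -> int:
    """miRNA/RBP site count: exact k-mer matches, optionally peak-restricted."""
    if not kmers:
        return 0
    widths = {len(k) for k in kmers}
    seq = utr_seq.upper()
    positions = sorted(_kmer_match_positions(seq, [k.upper() for k in kmers]))
    if peaks is None and no_peak_mode == "pass":
        return len(positions)
    w = max(widths)
    intervals = [GenomicInterval(chrom, region_start + i, region_start + i + w)
                 for i in positions]
    return len(intersect_with_peaks(intervals, peaks, background_regions,
                                    no_peak_mode=no_peak_mode))


def build_feature_counts(
    sequences: dict[str, str],
    annotations: pd.DataFrame,
    pfms: dict[str, list[PFM]],
    *,
    promoter_flank: int = 2000,
    fimo_p: float = 1e-4,
    rbp_top_kmers: int = 10,
    mirna_top_kmers: int = 1,
    background: np.ndarray | None = None,
    dnase_peaks: list[GenomicInterval] | None = None,
    clip_peaks: list[GenomicInterval] | None = None,
    clip_background: list[GenomicInterval] | None = None,
    tf_no_peak_mode: str = "pass",
    rbp_no_peak_mode: str = "pass",
) -> dict[str, pd.DataFrame]:
    """Per-class gene x regulator count tables from sequences + annotations.

    ``annotations`` columns: gene, chrom, tss, strand, utr_start, utr_end
    (0-based half-open).  Minus-strand genes have their 3'UTR sequence
    reverse-complemented before single-strand scanning.
    """
    counts: dict[str, pd.DataFrame] = {}
    genes = list(annotations["gene"])
    kmer_cache: dict[tuple[str, int], list[str]] = {}
    for cls in REGULATOR_CLASSES:
        mats = pfms.get(cls, [])
        if not mats:
            continue
        table = np.zeros((len(genes), len(mats)), dtype=int)
        for gi, row in enumerate(annotations.itertuples(index=False)):
            chrom_seq = sequences[row.chrom]
            if cls == "TF":
                region = promoter_region(int(row.tss), row.strand,
                                         promoter_flank, row.chrom)
                seq = chrom_seq[region.start:min(region.end, len(chrom_seq))]
                for mi, pfm in enumerate(mats):
                    table[gi, mi] = count_tf_sites(
                        seq, pfm, fimo_p, background,
                        chrom=row.chrom, region_start=region.start,
                        dnase_peaks=dnase_peaks, no_peak_mode=tf_no_peak_mode)
            else:
                utr = chrom_seq[int(row.utr_start):int(row.utr_end)]
                if row.strand == "-":
                    utr = reverse_complement(utr)
                n_top = mirna_top_kmers if cls == "MIRNA" else rbp_top_kmers
                for mi, pfm in enumerate(mats):
                    key = (f"{cls}:{pfm.name}", n_top)
                    if key not in kmer_cache:
                        kmer_cache[key] = top_kmers(pfm, n_top)
                    peaks = clip_peaks if cls == "RBP" else None
                    bg_regions = clip_background if cls == "RBP" else None
                    mode = rbp_no_peak_mode if cls == "RBP" else "pass"
                    table[gi, mi] = count_utr_kmer_sites(
                        utr, kmer_cache[key],
                        chrom=row.chrom, region_start=int(row.utr_start),
                        peaks=peaks, background_regions=bg_regions,
                        no_peak_mode=mode)
        counts[cls] = pd.DataFrame(table, index=pd.Index(genes, name="gene"),
                                   columns=[m.name for m in mats])
    return counts
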