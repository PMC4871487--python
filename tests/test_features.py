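"""Motif scanning, k-mer ranking, interval filtering and matrix assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from regnet import (
    PFM,
    GenomicInterval,
    assemble_feature_matrix,
    count_kmer_sites,
    intersect_with_peaks,
    merge_identical_features,
    promoter_region,
    scan_pfm,
    top_kmers,
)
from regnet.features import FeatureMatrix, reverse_complement
from regnet.io import read_jaspar, write_jaspar


class TestPromoterRegion:
    def test_symmetric_flank(self):
        iv = promoter_region(5000, "+", 2000)
        assert (iv.start, iv.end) == (3000, 7000)

    def test_clipped_at_chromosome_start(self):
        iv = promoter_region(100, "-", 2000)
        assert (iv.start, iv.end) == (0, 2100)

    def test_zero_flank_rejected(self):
        with pytest.raises(ValueError):
            promoter_region(100, "+", 0)

    def test_strand_independent_extent(self):
        a = promoter_region(500, "+", 100)
        b = promoter_region(500, "-", 100)
        assert (a.start, a.end) == (b.start, b.end)


class TestScanPFM:
    def test_width2_pvalues_match_enumeration(self):
        """Exact DP p-values equal brute-force enumeration over all 16
        dinucleotides (same integerised scores)."""
        rng = np.random.default_rng(1)
        pfm = PFM("w2", rng.dirichlet(np.ones(4), size=2))
        table = pfm.score_table(None, 1000)
        kmers = list(itertools.product(range(4), repeat=2))
        ints = np.array([table.int_scores[0, a] + table.int_scores[1, b]
                         for a, b in kmers])
        enum_p = np.array([(ints >= s).mean() for s in ints])
        assert np.array_equal(table.pvalue_of_int(ints), enum_p)

    @pytest.mark.parametrize("width", [3, 4, 5, 6])
    def test_dp_matches_enumeration_exactly(self, width):
        rng = np.random.default_rng(width)
        pfm = PFM(f"w{width}", rng.dirichlet(np.ones(4), size=width))
        table = pfm.score_table(None, 1000)
        kmers = np.array(list(itertools.product(range(4), repeat=width)))
        ints = table.int_scores[np.arange(width)[None, :], kmers].sum(axis=1)
        enum_p = np.array([(ints >= s).mean() for s in ints])
        assert np.array_equal(table.pvalue_of_int(ints), enum_p)

    def test_float_enumeration_agreement_at_moderate_p(self):
        """Against float-score enumeration the binned p-values agree closely
        wherever the tail is not a handful of k-mers."""
        rng = np.random.default_rng(2)
        width = 5
        pfm = PFM("w5", rng.dirichlet(np.ones(4), size=width))
        table = pfm.score_table(None, 1000)
        kmers = np.array(list(itertools.product(range(4), repeat=width)))
        pos = np.arange(width)[None, :]
        ints = table.int_scores[pos, kmers].sum(axis=1)
        floats = table.float_scores[pos, kmers].sum(axis=1)
        p_float = np.array([(floats >= s - 1e-12).mean() for s in floats])
        p_dp = table.pvalue_of_int(ints)
        sel = p_float >= 0.05
        assert np.max(np.abs(p_dp[sel] - p_float[sel]) / p_float[sel]) < 0.05

    def test_consensus_limit(self):
        """A near-deterministic PFM hits exactly the consensus occurrences."""
        pfm = PFM.from_consensus("m", "ACGT", match_prob=0.97)
        seq = "TTACGTTTACGTACGTTT"
        hits = scan_pfm(seq, pfm, 1e-2)
        starts = [h.offset for h in hits]
        expected = [i for i in range(len(seq) - 3) if seq[i:i + 4] == "ACGT"]
        assert starts == expected

    def test_both_strands_reports_reverse_complement_match(self):
        pfm = PFM.from_consensus("m", "AACCGG", match_prob=0.97)
        rc = reverse_complement("AACCGG")
        seq = "TTTT" + rc + "TTTT"
        fwd = scan_pfm(seq, pfm, 1e-3, both_strands=False)
        both = scan_pfm(seq, pfm, 1e-3, both_strands=True)
        assert fwd == []
        assert [(h.offset, h.strand) for h in both] == [(4, "-")]

    def test_vacuous_threshold_reports_every_window(self):
        rng = np.random.default_rng(0)
        pfm = PFM("m", rng.dirichlet(np.ones(4), size=3))
        seq = "ACGTACGTAC"
        hits = scan_pfm(seq, pfm, 1.0)
        assert len(hits) == len(seq) - 2

    def test_empty_and_short_sequences(self):
        pfm = PFM.from_consensus("m", "ACGT")
        assert scan_pfm("", pfm) == []
        assert scan_pfm("AC", pfm) == []

    def test_invalid_characters_skip_windows(self):
        pfm = PFM.from_consensus("m", "ACGT", match_prob=0.97)
        hits = scan_pfm("ACNTACGT", pfm, 1e-2)
        assert [h.offset for h in hits] == [4]


class TestTopKmers:
    def test_deterministic_pfm_ranking_matches_enumeration(self):
        rng = np.random.default_rng(4)
        pfm = PFM("m", rng.dirichlet((8, 1, 1, 1), size=4))
        got = top_kmers(pfm, 10)
        # exhaustive oracle: all 4^k, sorted by (-prob, kmer)
        all_kmers = ["".join(k) for k in itertools.product("ACGT", repeat=4)]
        idx = {b: i for i, b in enumerate("ACGT")}
        probs = [np.prod([pfm.probs[i, idx[b]] for i, b in enumerate(k)])
                 for k in all_kmers]
        expected = [k for _, k in sorted(zip([-p for p in probs], all_kmers))][:10]
        assert got == expected
        assert got[0] == pfm.consensus()

    def test_uniform_pfm_ties_break_lexicographically(self):
        pfm = PFM("u", np.full((3, 4), 0.25))
        got = top_kmers(pfm, 10)
        expected = ["".join(k) for k in itertools.product("ACGT", repeat=3)][:10]
        assert got == expected

    def test_n_exceeding_space_returns_all(self):
        pfm = PFM("u", np.full((2, 4), 0.25))
        assert len(top_kmers(pfm, 100)) == 16

    def test_width_bound(self):
        pfm = PFM("u", np.full((13, 4), 0.25))
        with pytest.raises(ValueError):
            top_kmers(pfm, 5)


class TestCountKmerSites:
    def test_overlapping_matches_counted(self):
        assert count_kmer_sites("ACGTACGTACGT", ["ACGT"]) == 3
        assert count_kmer_sites("AAAA", ["AA"]) == 3

    def test_empty_kmer_list(self):
        assert count_kmer_sites("ACGT", []) == 0

    def test_position_counted_once_for_multiple_kmers(self):
        assert count_kmer_sites("ACGT", ["ACG", "ACGT"]) == 1


class TestIntersectWithPeaks:
    def test_background_splits_peak(self):
        """Peak [0,50) minus background [15,20) still overlaps hit [10,17)."""
        hit = GenomicInterval("c", 10, 17)
        kept = intersect_with_peaks([hit], [GenomicInterval("c", 0, 50)],
                                    [GenomicInterval("c", 15, 20)])
        assert kept == [hit]

    def test_hit_fully_inside_background_dropped(self):
        hit = GenomicInterval("c", 16, 19)
        kept = intersect_with_peaks([hit], [GenomicInterval("c", 0, 50)],
                                    [GenomicInterval("c", 15, 20)])
        assert kept == []

    def test_background_covering_peak_drops_everything(self):
        hits = [GenomicInterval("c", 5, 9), GenomicInterval("c", 30, 34)]
        kept = intersect_with_peaks(hits, [GenomicInterval("c", 0, 40)],
                                    [GenomicInterval("c", 0, 40)])
        assert kept == []

    def test_no_peak_modes(self):
        hits = [GenomicInterval("c", 5, 9)]
        assert intersect_with_peaks(hits, None, no_peak_mode="pass") == hits
        assert intersect_with_peaks(hits, None, no_peak_mode="drop") == []

    def test_malformed_interval_names_record(self):
        with pytest.raises(ValueError, match="chrX:20-10"):
            GenomicInterval("chrX", 20, 10)


def _fm(values: pd.DataFrame, classes=None) -> FeatureMatrix:
    classes = classes or {c: "TF" for c in values.columns}
    return FeatureMatrix(values=values, classes=classes)


class TestAssembleAndMerge:
    def _sources(self):
        genes = ["g1", "g2", "g3"]
        counts = {"TF": pd.DataFrame({"TF_a": [1, 0, 2], "TF_b": [0, 0, 0]},
                                     index=genes)}
        cnv = pd.Series([0.1, -1.0, 0.0], index=genes)
        meth = pd.Series([0.5, 0.2, 0.9], index=genes)
        return counts, cnv, meth

    def test_all_zero_regulator_removed(self):
        counts, cnv, meth = self._sources()
        fm = assemble_feature_matrix(counts, cnv, meth)
        assert "TF_b" not in fm.values.columns
        assert list(fm.values.columns) == ["CNV", "METH", "TF_a"]

    def test_gene_missing_from_cnv_dropped(self):
        counts, cnv, meth = self._sources()
        fm = assemble_feature_matrix(counts, cnv.drop("g2"), meth)
        assert fm.genes == ["g1", "g3"]

    def test_disjoint_gene_sets_error(self):
        counts, cnv, meth = self._sources()
        cnv.index = ["x1", "x2", "x3"]
        with pytest.raises(ValueError):
            assemble_feature_matrix(counts, cnv, meth)

    def test_merge_collapses_duplicates(self):
        values = pd.DataFrame({"f1": [1, 2, 3], "f2": [1, 2, 3], "f3": [0, 0, 1]},
                              index=["g1", "g2", "g3"], dtype=float)
        merged = merge_identical_features(_fm(values))
        assert list(merged.values.columns) == ["f1", "f3"]
        assert merged.merged_members["f1"] == ["f1", "f2"]

    def test_merge_identity_when_distinct(self):
        values = pd.DataFrame({"f1": [1.0, 2.0], "f2": [2.0, 1.0]}, index=["a", "b"])
        merged = merge_identical_features(_fm(values))
        assert list(merged.values.columns) == ["f1", "f2"]

    def test_full_collapse(self):
        values = pd.DataFrame({f"f{i}": [1.0, 0.0] for i in range(5)},
                              index=["a", "b"])
        merged = merge_identical_features(_fm(values))
        assert merged.values.shape[1] == 1
        assert len(merged.merged_members["f0"]) == 5

    @given(st.integers(0, 2**32 - 1))
    def test_merge_idempotent_and_column_preserving(self, seed):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(
            rng.integers(0, 2, size=(4, 6)).astype(float),
            index=[f"g{i}" for i in range(4)],
            columns=[f"f{i}" for i in range(6)],
        )
        fm = _fm(values)
        once = merge_identical_features(fm)
        twice = merge_identical_features(once)
        assert once.values.equals(twice.values)
        assert once.merged_members == twice.merged_members
        # multiset of distinct columns preserved
        before = {tuple(values[c]) for c in values.columns}
        after = {tuple(once.values[c]) for c in once.values.columns}
        assert before == after


def test_jaspar_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    pfms = [PFM("M1", rng.dirichlet(np.ones(4), size=6)),
            PFM.from_consensus("M2", "ACGTAA")]
    path = tmp_path / "motifs.jaspar"
    write_jaspar(pfms, path)
    back = read_jaspar(path)
    assert [p.name for p in back] == ["M1", "M2"]
    for a, b in zip(pfms, back):
        assert a.width == b.width
        assert np.allclose(a.probs, b.probs, atol=2e-3)
    assert back[1].consensus() == "ACGTAA"
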