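"""Leave-one-regulator-out error changes, permutation nulls and target calls."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from regnet import (
    call_targets,
    delta_error,
    ecdf_groups,
    empirical_pvalues,
    make_validation_groups,
    overlap_report,
    permutation_null,
    summed_delta_error,
)
from regnet.lasso import RegressionFit
from regnet.targets import NullDistribution

from oracles import permutation_null_bruteforce


def _fit(coefs, names, intercept=0.0):
    return RegressionFit(intercept=intercept, coefficients=coefs, lam=0.1,
                         feature_names=names)


class TestDeltaError:
    def test_zero_coefficient_gives_zero_vector(self, rng):
        X = pd.DataFrame(rng.poisson(1.0, size=(10, 2)).astype(float),
                         columns=["r", "o"])
        fit = _fit({"o": 1.0}, ["r", "o"])
        y = fit.predict(X)
        assert np.array_equal(delta_error(fit, X, y, "r"), np.zeros(10))

    def test_perfect_fit_single_gene(self):
        """With zero residual and contribution 2, the change is (0+2)^2 = 4."""
        X = pd.DataFrame({"r": [1.0]})
        fit = _fit({"r": 2.0}, ["r"])
        y = fit.predict(X)  # exact fit
        assert delta_error(fit, X, y, "r")[0] == pytest.approx(4.0)

    def test_matches_direct_recomputation(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        fit = _fit({"a": 0.7, "c": -1.2}, list("abc"), intercept=2.0)
        y = rng.normal(size=10)
        got = delta_error(fit, X, y, "c")
        yhat = 2.0 + 0.7 * X["a"] - 1.2 * X["c"]
        yhat_wo = yhat + 1.2 * X["c"]
        expected = (y - yhat_wo) ** 2 - (y - yhat) ** 2
        assert np.allclose(got, expected)

    def test_unknown_regulator(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 1)), columns=["a"])
        with pytest.raises(ValueError):
            delta_error(_fit({"a": 1.0}, ["a"]), X, np.zeros(5), "zzz")

    def test_zero_count_gene_unchanged(self, rng):
        X = pd.DataFrame({"r": [0.0, 2.0, 0.0], "o": [1.0, 1.0, 1.0]})
        fit = _fit({"r": 1.5, "o": 0.3}, ["r", "o"])
        d = delta_error(fit, X, rng.normal(size=3), "r")
        assert d[0] == 0.0 and d[2] == 0.0 and d[1] != 0.0


class TestSummedDeltaError:
    def _setup(self, rng):
        X = pd.DataFrame(rng.poisson(1.0, size=(8, 2)).astype(float),
                         columns=["r", "o"])
        fit = _fit({"r": 1.0, "o": -0.5}, ["r", "o"])
        y = rng.normal(size=8)
        return X, fit, y

    def test_single_sample_equals_delta(self, rng):
        X, fit, y = self._setup(rng)
        assert np.allclose(summed_delta_error([fit], X, [y], "r"),
                           delta_error(fit, X, y, "r"))

    def test_two_identical_samples_double(self, rng):
        X, fit, y = self._setup(rng)
        assert np.allclose(summed_delta_error([fit, fit], X, [y, y], "r"),
                           2 * delta_error(fit, X, y, "r"))

    def test_sample_order_invariance(self, rng):
        X, fit, y = self._setup(rng)
        y2 = rng.normal(size=8)
        a = summed_delta_error([fit, fit], X, [y, y2], "r")
        b = summed_delta_error([fit, fit], X, [y2, y], "r")
        assert np.allclose(a, b)


class TestPermutationNull:
    def test_identity_permutation_reproduces_observed(self, rng):
        X = pd.DataFrame(rng.poisson(1.0, size=(12, 3)).astype(float),
                         columns=list("abc"))
        fit = _fit({"a": 1.0, "b": -2.0}, list("abc"), intercept=1.0)
        y = rng.normal(size=12)

        def identity(rng_, b, n, k):
            return np.tile(np.arange(n)[None, :, None], (b, 1, k))

        null = permutation_null(X, [y], [fit], "a", B=1, seed=0, perm_fn=identity)
        observed = summed_delta_error([fit], X, [y], "a")
        assert np.allclose(null.samples[0], observed)

    def test_constant_column_is_permutation_invariant(self, rng):
        X = pd.DataFrame({"r": np.full(10, 2.0), "o": np.full(10, 3.0)})
        fit = _fit({"r": 1.0, "o": 0.5}, ["r", "o"])
        y = rng.normal(size=10)
        null = permutation_null(X, [y], [fit], "r", B=20, seed=1)
        observed = summed_delta_error([fit], X, [y], "r")
        assert np.allclose(null.samples, observed[None, :])

    def test_matches_bruteforce_oracle(self, rng):
        """Vectorised null equals a gene-by-gene loop re-implementation."""
        X = pd.DataFrame(rng.poisson(1.2, size=(20, 4)).astype(float),
                         columns=list("abcd"))
        fits = [_fit({"a": 1.0, "c": -0.8}, list("abcd"), intercept=2.0),
                _fit({"a": 1.2, "d": 0.4}, list("abcd"), intercept=1.5)]
        ys = [rng.normal(size=20), rng.normal(size=20)]
        null = permutation_null(X, ys, fits, "a", B=30, seed=7)
        brute = permutation_null_bruteforce(X, ys, fits, "a", B=30, seed=7)
        assert np.allclose(null.samples, brute)

    def test_seeded_determinism(self, rng):
        X = pd.DataFrame(rng.poisson(1.0, size=(10, 2)).astype(float),
                         columns=["r", "o"])
        fit = _fit({"r": 1.0}, ["r", "o"])
        y = rng.normal(size=10)
        a = permutation_null(X, [y], [fit], "r", B=10, seed=3)
        b = permutation_null(X, [y], [fit], "r", B=10, seed=3)
        assert np.array_equal(a.samples, b.samples)


class TestEmpiricalPvalues:
    def _null(self, values):
        values = np.asarray(values, float)
        return NullDistribution("r", values.shape[0], values,
                                [f"g{i}" for i in range(values.shape[1])])

    def test_observed_above_all_nulls(self):
        null = self._null(np.zeros((5000, 1)))
        p = empirical_pvalues(np.array([1.0]), null)
        assert p[0] == pytest.approx(1 / 5001)

    def test_observed_below_all_nulls(self):
        null = self._null(np.ones((10, 1)))
        assert empirical_pvalues(np.array([0.0]), null)[0] == 1.0

    def test_hand_enumeration_b10(self):
        nulls = np.array([[0, 1, 2, 3, 4, 5, 6, 7, 8, 9]], float).T  # B=10, 1 gene
        p = empirical_pvalues(np.array([4.5]), self._null(nulls))
        # nulls >= 4.5 are {5..9}: 5 of 10 -> (1+5)/11
        assert p[0] == pytest.approx(6 / 11)

    def test_ties_count_as_exceedance(self):
        nulls = np.zeros((4, 1))
        assert empirical_pvalues(np.array([0.0]), self._null(nulls))[0] == 1.0


class TestCallTargets:
    def test_all_p_one_calls_nothing(self):
        p = pd.Series(np.ones(20), index=[f"g{i}" for i in range(20)])
        out = call_targets(p, q_threshold=0.05)
        assert not out["is_target"].any()

    def test_vacuous_threshold_calls_everything(self):
        p = pd.Series(np.linspace(0.01, 1.0, 10), index=[f"g{i}" for i in range(10)])
        out = call_targets(p, q_threshold=1.0)
        assert out["is_target"].all()

    def test_bh_tied_block_qvalues(self):
        """100 genes, ten at the B=5000 floor p=1/5001: the BH q of the tied
        block is p*m/k = 1/5001 * 100/10 ~ 2e-3, so nothing passes q <= 2e-4
        but exactly those ten pass q <= 0.01 (cross-checked with statsmodels)."""
        p = np.ones(100)
        p[:10] = 1 / 5001
        ps = pd.Series(p, index=[f"g{i}" for i in range(100)])
        out = call_targets(ps, q_threshold=2e-4).set_index("gene")
        assert not out["is_target"].any()
        q_expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(np.sort(out["q_value"]), np.sort(q_expected))
        out2 = call_targets(ps, q_threshold=0.01)
        called = set(out2.loc[out2["is_target"], "gene"])
        assert called == {f"g{i}" for i in range(10)}

    def test_positive_evidence_required_when_deltas_given(self):
        p = pd.Series([1 / 5001, 1 / 5001], index=["g0", "g1"])
        deltas = pd.Series([5.0, 0.0], index=["g0", "g1"])
        out = call_targets(p, q_threshold=0.05, deltas=deltas).set_index("gene")
        assert bool(out.loc["g0", "is_target"])
        assert not bool(out.loc["g1", "is_target"])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            call_targets(pd.Series([0.0, 0.5], index=["a", "b"]))


class TestOverlapReport:
    def test_disjoint(self):
        rep = overlap_report({"a", "b"}, {"c"})
        assert rep["n_intersection"] == 0
        assert rep["fraction_predicted_in_reference"] == 0.0

    def test_subset(self):
        rep = overlap_report({"a", "b"}, {"a", "b", "c"})
        assert rep["fraction_predicted_in_reference"] == 1.0

    def test_hand_count(self):
        rep = overlap_report({"a", "b", "c", "d"}, {"c", "d", "e"})
        assert rep["n_intersection"] == 2
        assert rep["fraction_predicted_in_reference"] == 0.5

    def test_empty_prediction_warns(self):
        with pytest.warns(UserWarning):
            rep = overlap_report(set(), {"a"})
        assert rep["fraction_predicted_in_reference"] == 0.0


class TestEcdfGroups:
    def test_partition_construction(self):
        genes = [f"g{i}" for i in range(10)]
        groups = make_validation_groups(
            genes, reference_targets={"g0", "g1"},
            predicted_targets={"g1", "g2"}, motif_genes={"g0", "g1", "g2", "g3"})
        all_assigned = set().union(*groups.values())
        assert all_assigned == set(genes)
        sizes = sum(len(g) for g in groups.values())
        assert sizes == len(genes)  # disjoint
        assert groups["reference_targets"] == {"g0", "g1"}
        assert groups["predicted_targets"] == {"g2"}
        assert groups["motif_only"] == {"g3"}

    def test_overlapping_groups_rejected(self, rng):
        lfc = pd.Series(rng.normal(size=4), index=list("abcd"))
        with pytest.raises(ValueError):
            ecdf_groups(lfc, {"x": {"a", "b"}, "y": {"b", "c"}})

    def test_identical_distributions_have_small_ks(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(2000)]
        lfc = pd.Series(rng.normal(size=2000), index=genes)
        res = ecdf_groups(lfc, {"a": set(genes[:1000]), "b": set(genes[1000:])})
        assert res["ks"]["ks_statistic"].iloc[0] <= 0.1

    def test_shifted_group_dominates(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(400)]
        vals = rng.normal(size=400)
        vals[:200] += 1.0
        lfc = pd.Series(vals, index=genes)
        res = ecdf_groups(lfc, {"shifted": set(genes[:200]),
                                "null": set(genes[200:])})
        assert res["ks"]["ks_statistic"].iloc[0] >= 0.3
        # the shifted group's ECDF lies below (stochastic dominance)
        diff = res["ecdf"]["shifted"] - res["ecdf"]["null"]
        assert diff.mean() < 0

    def test_empty_group_warns_and_skips(self, rng):
        lfc = pd.Series(rng.normal(size=3), index=list("abc"))
        with pytest.warns(UserWarning):
            res = ecdf_groups(lfc, {"x": {"a", "b", "c"}, "y": set()})
        assert "y" not in res["ecdf"]
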