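"""Cross-validation schemes, ROC metrics, DeLong, Monte-Carlo CIs, ensembles."""

import numpy as np
import pytest
from scipy import stats

from longisym.errors import (
    ConfigurationError,
    NumericalDegeneracyError,
    UndefinedMetricError,
)
from longisym.evalstats import (
    CvScheme,
    ScoreSet,
    auc,
    choose_cutoff,
    delong_test,
    ensemble_score,
    evaluate_scores,
    make_splits,
    mc_confidence_interval,
)
from tests.oracles import exhaustive_min_corner_cutoff, pair_count_auc


class TestMakeSplits:
    def test_repeated_scheme_tests_each_subject_once_per_repeat(self):
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        scheme = CvScheme(kind="repeated_10fold", n_repeats=5, seed=0)
        repeats = make_splits(y, scheme)
        assert len(repeats) == 5
        counts = np.zeros(60, int)
        for folds in repeats:
            seen = np.zeros(60, int)
            for _, te in folds:
                seen[te] += 1
            assert np.all(seen == 1)
            counts += seen
        assert np.all(counts == 5)

    def test_single_scheme_partitions_disjointly(self):
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        scheme = CvScheme(kind="single_10fold_with_val", seed=1)
        for tr, va, te in make_splits(y, scheme):
            assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))
            assert len(tr) + len(va) + len(te) == 40
            # stratification keeps both classes in every partition
            assert {0, 1} == set(y[tr]) and {0, 1} <= set(y[tr])

    def test_deterministic_for_seed(self):
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        scheme = CvScheme(kind="repeated_10fold", n_repeats=2, seed=3)
        a = make_splits(y, scheme)
        b = make_splits(y, scheme)
        for fa, fb in zip(a, b):
            for (tra, tea), (trb, teb) in zip(fa, fb):
                np.testing.assert_array_equal(tra, trb)
                np.testing.assert_array_equal(tea, teb)

    def test_too_few_subjects_raises(self):
        y = np.r_[np.zeros(4, int), np.ones(30, int)]
        with pytest.raises(ConfigurationError):
            make_splits(y, CvScheme())


class TestAuc:
    def test_worked_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_matches_bruteforce_pair_counting(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = rng.integers(6, 30)
            y = rng.integers(0, 2, size=n)
            if len(set(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # rounding forces ties
            assert abs(auc(s, y) - pair_count_auc(s, y)) < 1e-12

    def test_complement_property_without_ties(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=25)
        y[:2] = [0, 1]
        s = rng.permutation(np.linspace(0.01, 0.99, 25))
        assert auc(1 - s, y) == pytest.approx(1 - auc(s, y), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.1, 0.2], [1, 1])


class TestChooseCutoff:
    def test_perfect_classifier_hits_the_corner(self):
        t, sens, spec, bal = choose_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert (sens, spec, bal) == (1.0, 1.0, 1.0)
        assert t == 0.8

    def test_worked_example_tie_breaks_to_lower_threshold(self):
        t, sens, spec, bal = choose_cutoff([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert t == 0.35
        assert (sens, spec) == (1.0, 0.5)
        assert bal == 0.75

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            n = rng.integers(8, 40)
            y = rng.integers(0, 2, size=n)
            if len(set(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)
            t, sens, spec, _ = choose_cutoff(s, y)
            ot, osens, ospec = exhaustive_min_corner_cutoff(s, y)
            assert t == ot and sens == osens and spec == ospec


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        y = [0, 1, 0, 1, 1, 0]
        s = [0.2, 0.7, 0.4, 0.9, 0.6, 0.1]
        a, b, p = delong_test(s, s, y)
        assert a == b and p == 1.0

    def test_swap_gives_same_p(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        sa = rng.random(20)
        sb = np.clip(sa + rng.normal(0, 0.2, 20), 0, 1)
        _, _, p1 = delong_test(sa, sb, y)
        _, _, p2 = delong_test(sb, sa, y)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_p_uniform_under_null(self):
        """DeLong p-values on exchangeable paired scores are ~ Uniform(0,1)."""
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(500):
            y = np.r_[np.zeros(20, int), np.ones(20, int)]
            base = rng.normal(size=40) + y  # informative but identical for a and b
            sa = base + rng.normal(0, 0.5, 40)
            sb = base + rng.normal(0, 0.5, 40)
            _, _, p = delong_test(sa, sb, y)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_variance_with_unequal_aucs_raises(self):
        y = [0, 0, 1, 1]
        with pytest.raises((NumericalDegeneracyError, UndefinedMetricError)):
            # constant per-group structure: zero variance, different AUCs
            delong_test([0.1, 0.2, 0.8, 0.9], [0.9, 0.8, 0.2, 0.1], y)


class TestMonteCarloCI:
    def test_perfect_scores_give_degenerate_interval(self):
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        s = np.r_[np.linspace(0, 0.4, 10), np.linspace(0.6, 1.0, 10)]
        assert mc_confidence_interval(s, y, iters=200, seed=0) == (1.0, 1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        s = rng.random(30)
        a = mc_confidence_interval(s, y, iters=100, seed=9)
        b = mc_confidence_interval(s, y, iters=100, seed=9)
        assert a == b

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(6)
        widths = {}
        for n in (40, 400):
            y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
            s = np.clip(0.35 + 0.3 * y + rng.normal(0, 0.25, n), 0, 1)
            lo, hi = mc_confidence_interval(s, y, iters=300, seed=1)
            widths[n] = hi - lo
        assert widths[400] < widths[40]


class TestEnsembleScore:
    class _Const:
        def __init__(self, value):
            self.value = value

        def predict_proba(self, x1, x2):
            return np.full(len(x1), self.value)

    def test_identical_models_equal_single_model(self):
        pairs = [(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))] * 3
        models = [self._Const(0.7)] * 10
        out = ensemble_score(models, pairs)
        np.testing.assert_allclose(out.probabilities, 0.7)
        assert np.all(out.n_predictions == 10)

    def test_mean_of_mixed_models(self):
        pairs = [(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))]
        models = [self._Const(0.2)] * 5 + [self._Const(0.6)] * 5
        out = ensemble_score(models, pairs)
        assert out.probabilities[0] == pytest.approx(0.4)

    def test_incomplete_model_set_raises(self):
        with pytest.raises(ConfigurationError):
            ensemble_score([self._Const(0.5)] * 7, [])


def test_evaluate_scores_report_is_consistent():
    rng = np.random.default_rng(7)
    y = np.r_[np.zeros(25, int), np.ones(25, int)]
    s = np.clip(0.3 + 0.4 * y + rng.normal(0, 0.2, 50), 0, 1)
    rep = evaluate_scores(s, y, ci_iters=200, seed=0)
    assert rep.ci_low <= rep.auc <= rep.ci_high
    assert rep.balanced_accuracy == pytest.approx((rep.sensitivity + rep.specificity) / 2)
    assert 0 <= rep.auc <= 1


def test_scoreset_validation():
    with pytest.raises(Exception):
        ScoreSet(["a"], np.array([1.7]), np.array([1]), np.array([1]))
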