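"""Evaluation statistics: exact binomial CIs, ROC/AUC, kappa, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

import ngtlife as ng
from ngtlife.evaluate import (CalibrationResult, brier_score, clopper_pearson,
                              round_half_up)


def _auc_pairwise_oracle(scores, labels):
    """Brute force over all positive-negative pairs; ties count half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = wins = 0.0
    for p in pos:
        for q in neg:
            total += 1
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / total


class TestClopperPearson:
    def test_printed_sensitivity_counts(self):
        # 19 of 24 -> 79% with lower bound 58%
        lo, hi = clopper_pearson(19, 24)
        assert int(round_half_up(19 / 24 * 100)) == 79
        assert int(round_half_up(lo * 100)) == 58

    def test_printed_accuracy_counts(self):
        # 345 of 355 -> 97% (95% CI: 95%, 99%)
        lo, hi = clopper_pearson(345, 355)
        assert int(round_half_up(345 / 355 * 100)) == 97
        assert (int(round_half_up(lo * 100)), int(round_half_up(hi * 100))) == (95, 99)

    def test_boundaries_closed(self):
        lo, _ = clopper_pearson(0, 20)
        assert lo == 0.0
        _, hi = clopper_pearson(20, 20)
        assert hi == 1.0

    def test_interval_brackets_estimate(self):
        for x, n in [(1, 10), (5, 10), (9, 10), (50, 355)]:
            lo, hi = clopper_pearson(x, n)
            assert lo <= x / n <= hi


class TestConfusionAndMetrics:
    def _cm(self):
        counts = np.array([[50, 5, 1], [8, 30, 2], [0, 1, 19]])
        return ng.ConfusionMatrix(counts, ng.CLASSES)

    def test_argmax_prediction_contract(self):
        proba = np.array([[0.5, 0.3, 0.2], [0.1, 0.6, 0.3], [0.2, 0.2, 0.6]])
        cm = ng.confusion(["satisfactory", "bronchial", "bronchial"], proba, ng.CLASSES)
        assert cm.counts[0, 0] == 1  # truth satisfactory, predicted satisfactory
        assert cm.counts[2, 1] == 1  # truth bronchial, predicted malpositioned
        assert cm.counts[2, 2] == 1
        assert cm.n == 3

    def test_one_vs_rest_counts(self):
        cm = self._cm()
        m = ng.class_metrics(cm, "bronchial")
        assert (m["sensitivity"].x, m["sensitivity"].n) == (19, 20)
        assert (m["ppv"].x, m["ppv"].n) == (19, 22)
        tn = cm.n - 20 - 3  # negatives minus false positives
        assert (m["specificity"].x, m["specificity"].n) == (tn, cm.n - 20)

    def test_percentages_reconstructible_from_counts(self):
        table = ng.metrics_table(self._cm())
        for _, row in table.iterrows():
            assert row["estimate"] == pytest.approx(row["x"] / row["n"])
            assert row["method"] == "clopper-pearson"

    def test_zero_denominator_flagged_not_nan(self):
        cm = ng.ConfusionMatrix(np.array([[3, 0], [2, 0]]), ("a", "b"))
        m = ng.class_metrics(cm, "b")
        assert not m["ppv"].defined


class TestRocAuc:
    def test_perfect_separation(self):
        res = ng.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], n_boot=20, seed=0)
        assert res.auc == 1.0

    def test_worked_example(self):
        res = ng.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], n_boot=20, seed=0)
        assert res.auc == pytest.approx(0.75)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        res = ng.roc_auc(rng.normal(size=500), rng.integers(0, 2, size=500),
                         n_boot=50, seed=0)
        assert res.auc == pytest.approx(0.5, abs=0.06)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            ng.roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_pairwise_oracle(self, data):
        n = data.draw(st.integers(6, 200))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        scores = rng.integers(0, 8, size=n) / 7.0  # coarse grid forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = ng.roc_auc(scores, labels, n_boot=5, seed=0)
        assert res.auc == pytest.approx(_auc_pairwise_oracle(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(42)
        scores = rng.normal(size=500)
        labels = (scores + rng.normal(0, 2, 500) > 0).astype(int)
        res = ng.roc_auc(scores, labels, n_boot=5, seed=0)
        assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_bootstrap_ci_coverage(self):
        # true AUC of N(0,1) vs N(delta,1) scores is Phi(delta/sqrt(2))
        from scipy.stats import norm
        delta = 1.0
        true_auc = norm.cdf(delta / np.sqrt(2))
        hits = 0
        reps = 200
        rng = np.random.default_rng(123)
        for r in range(reps):
            neg = rng.normal(0, 1, 60)
            pos = rng.normal(delta, 1, 60)
            res = ng.roc_auc(np.r_[neg, pos], np.r_[np.zeros(60), np.ones(60)],
                             n_boot=300, seed=r)
            hits += res.ci_low <= true_auc <= res.ci_high
        assert 0.90 <= hits / reps <= 0.99


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert ng.cohen_kappa(list("aabb"), list("aabb")).kappa == 1.0

    def test_hand_computed_cross_table(self):
        # cross-table [[20, 5], [10, 15]]: po=0.70, pe=0.50, kappa=0.40
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        res = ng.cohen_kappa(a, b)
        assert res.po == pytest.approx(0.70)
        assert res.pe == pytest.approx(0.50)
        assert res.kappa == pytest.approx(0.40)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.choice(["f", "d"], size=1000)
        b = rng.choice(["f", "d"], size=1000)
        assert abs(ng.cohen_kappa(a, b).kappa) < 0.08

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            ng.cohen_kappa(["a"], ["a", "b"])

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(6)
        a = rng.choice(list("xyz"), size=200)
        b = rng.choice(list("xyz"), size=200)
        assert ng.cohen_kappa(a, b).kappa == pytest.approx(ng.cohen_kappa(b, a).kappa)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(7)
        a = rng.choice(list("abc"), size=300)
        b = np.where(rng.random(300) < 0.6, a, rng.choice(list("abc"), size=300))
        assert ng.cohen_kappa(a, b).kappa == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_constant_identical_raters(self):
        assert ng.cohen_kappa(["f"] * 10, ["f"] * 10).kappa == 1.0


class TestKappaMatrix:
    def test_two_identical_readers(self):
        ratings = pd.DataFrame({"r1": list("ffdd"), "r2": list("ffdd")})
        mat, mean, sd = ng.kappa_matrix(ratings)
        assert np.allclose(mat.to_numpy(), 1.0)
        assert mean == 1.0 and sd == 0.0

    def test_three_reader_fixture_pairwise(self):
        ratings = pd.DataFrame({
            "r1": list("ffffdddd"),
            "r2": list("ffffdddf"),
            "r3": list("ffddddff"),
        })
        mat, mean, sd = ng.kappa_matrix(ratings)
        for i in ratings.columns:
            for j in ratings.columns:
                expect = ng.cohen_kappa(ratings[i], ratings[j]).kappa
                assert mat.loc[i, j] == pytest.approx(expect)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.allclose(np.diag(mat.to_numpy()), 1.0)
        off = [mat.iloc[0, 1], mat.iloc[0, 2], mat.iloc[1, 2]]
        assert mean == pytest.approx(np.mean(off))

    def test_reader_permutation_consistent(self):
        rng = np.random.default_rng(8)
        ratings = pd.DataFrame(rng.choice(["f", "d"], size=(40, 3)),
                               columns=["a", "b", "c"])
        mat, _, _ = ng.kappa_matrix(ratings)
        mat_perm, _, _ = ng.kappa_matrix(ratings[["c", "a", "b"]])
        assert mat_perm.loc["a", "b"] == pytest.approx(mat.loc["a", "b"])


class TestPairedKappaTest:
    def test_identical_conditions(self):
        t, p, df = ng.paired_kappa_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert t == 0.0 and p == 1.0 and df == 2

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.warns(UserWarning):
            t, p, df = ng.paired_kappa_test([0.5] * 5, [0.6] * 5)
        assert np.isinf(t) and p == 0.0 and df == 4

    def test_closed_form(self):
        d = np.array([0.12, 0.05, 0.2, 0.1, 0.13])
        unaided = np.array([0.5, 0.52, 0.48, 0.55, 0.5])
        t, p, df = ng.paired_kappa_test(unaided, unaided + d)
        expect = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(expect)
        assert df == 4

    def test_too_few_readers_raises(self):
        with pytest.raises(ValueError):
            ng.paired_kappa_test([0.5], [0.6])


class TestCalibration:
    def test_bernoulli_labels_are_calibrated(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, size=5000)
        y = rng.random(5000) < p
        res = ng.calibration_curve(p, y)
        assert res.ece < 0.03

    def test_certain_correct_predictions(self):
        res = ng.calibration_curve(np.ones(100), np.ones(100))
        assert res.ece == 0.0

    def test_constant_half_with_all_positive(self):
        res = ng.calibration_curve(np.full(100, 0.5), np.ones(100))
        assert res.ece == pytest.approx(0.5)

    def test_empty_bins_reported(self):
        res = ng.calibration_curve(np.full(50, 0.95), np.ones(50), bins=10)
        assert len(res.skipped_bins) == 9

    def test_out_of_range_probabilities_raise(self):
        with pytest.raises(ValueError):
            ng.calibration_curve([1.2], [1])


class TestFeedScore:
    def test_certain_satisfactory_scores_one(self):
        assert ng.feed_score((1.0, 0.0, 0.0)) == 1.0

    def test_certain_malposition_scores_zero(self):
        assert ng.feed_score((0.0, 0.6, 0.4)) == 0.0

    def test_malformed_triplet_raises(self):
        with pytest.raises(ValueError):
            ng.feed_score((0.5, 0.2, 0.1))

    def test_feed_roc_pipeline_composes(self):
        rng = np.random.default_rng(10)
        n = 300
        truth = rng.choice(["feed", "do_not_feed"], size=n)
        raw = rng.dirichlet(np.ones(3), size=n)
        raw[truth == "feed", 0] += 1.2
        proba = raw / raw.sum(axis=1, keepdims=True)
        scores = [ng.feed_score(tuple(row)) for row in proba]
        res = ng.roc_auc(scores, (truth == "feed").astype(int), n_boot=50, seed=1)
        assert 0.5 < res.auc <= 1.0


class TestBrier:
    def test_averaging_never_hurts_brier(self):
        # convexity: Brier(mean of models) <= mean of Briers
        rng = np.random.default_rng(11)
        y = rng.choice(ng.CLASSES, size=200)
        pa = rng.dirichlet(np.ones(3), size=200)
        pb = rng.dirichlet(np.ones(3), size=200)
        ens = (pa + pb) / 2
        assert brier_score(ens, y, ng.CLASSES) <= (
            brier_score(pa, y, ng.CLASSES) + brier_score(pb, y, ng.CLASSES)
        ) / 2 + 1e-12
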