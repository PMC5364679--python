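"""PR/ROC metrics against enumeration oracles, normalization laws, rebalancing,
cross-validation, and repeated holdout."""

import math

import numpy as np
import pytest

from lncsig.evaluation import (
    auc,
    classify,
    crossvalidate,
    min_aupr,
    normalized_aupr,
    pr_curve,
    rebalance,
    repeated_holdout,
    score_metrics,
)
from lncsig.synthetic_data import planted_feature_table


def aupr_oracle(scores, labels, grid=40001):
    """Threshold enumeration + dense interpolation of the PR integral.

    Operating points are enumerated exhaustively; between consecutive points
    FP is interpolated linearly in TP and precision integrated over recall
    on a dense grid (trapezoid), converging to the analytic segment areas.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    P = labels.sum()
    pts = [(0.0, 0.0)]
    for t in sorted(set(scores), reverse=True):
        mask = scores >= t
        pts.append((float((labels[mask] == 1).sum()), float((labels[mask] == 0).sum())))
    tps = np.array([p[0] for p in pts])
    fps = np.array([p[1] for p in pts])
    grid_tp = np.linspace(0, tps[-1], grid)[1:]
    grid_fp = np.interp(grid_tp, tps, fps)
    prec = grid_tp / (grid_tp + grid_fp)
    rec = grid_tp / P
    return float(np.trapezoid(prec, rec) + rec[0] * prec[0])


class TestPrCurve:
    def test_perfect_ranking_any_skew(self):
        for n_pos in (1, 3, 5):
            labels = np.r_[np.ones(n_pos), np.zeros(10)].astype(int)
            scores = -np.arange(len(labels), dtype=float)
            assert pr_curve(scores, labels).aupr_raw == pytest.approx(1.0)

    def test_constant_scores_collapse_to_skew(self):
        labels = np.r_[np.ones(3), np.zeros(9)].astype(int)
        m = pr_curve(np.zeros(12), labels)
        assert m.aupr_raw == pytest.approx(0.25)
        assert len(m.recall) == 1

    def test_six_sample_worked_case_matches_oracle(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        labels = np.array([1, 1, 0, 1, 0, 0])
        m = pr_curve(scores, labels)
        assert m.aupr_raw == pytest.approx(aupr_oracle(scores, labels), abs=1e-4)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            n = int(rng.integers(8, 50))
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False)] = 1
            scores = np.round(rng.random(n), 2)  # rounded -> exercises tie handling
            if labels.sum() in (0, n):
                continue
            m = pr_curve(scores, labels)
            assert m.aupr_raw == pytest.approx(aupr_oracle(scores, labels), abs=2e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            pr_curve(np.arange(4.0), np.ones(4, dtype=int))


class TestMinAupr:
    def test_closed_form_at_half(self):
        assert min_aupr(0.5) == pytest.approx(1 - math.log(2), abs=1e-9)

    def test_numerical_integration_agreement(self):
        from scipy.integrate import quad

        for pi in (0.05, 0.1, 0.3, 0.7):
            numeric, _ = quad(lambda r: pi * r / (pi * r + 1 - pi), 0, 1)
            assert min_aupr(pi) == pytest.approx(numeric, abs=1e-8)

    def test_limits_and_monotonicity(self):
        assert min_aupr(1e-9) == pytest.approx(0.0, abs=1e-8)
        grid = np.linspace(0.01, 0.99, 99)
        vals = [min_aupr(p) for p in grid]
        assert np.all(np.diff(vals) > 0)
        with pytest.raises(ValueError):
            min_aupr(0.0)


class TestNormalizedAupr:
    def test_endpoints(self):
        assert normalized_aupr(1.0, 0.3) == pytest.approx(1.0)
        assert normalized_aupr(min_aupr(0.3), 0.3) == pytest.approx(0.0)

    def test_algebraic_midpoint_at_half(self):
        lo = min_aupr(0.5)
        raw = lo + 0.5 * (1 - lo)  # = 0.6534... by construction
        assert raw == pytest.approx(0.6534, abs=1e-4)
        assert normalized_aupr(raw, 0.5) == pytest.approx(0.5)

    def test_strictly_monotone_in_raw(self):
        for pi in (0.1, 0.5):
            raws = np.linspace(min_aupr(pi), 1.0, 50)
            vals = [normalized_aupr(r, pi) for r in raws]
            assert np.all(np.diff(vals) > 0)


class TestAuc:
    def test_perfect_and_reversed(self):
        labels = np.array([0, 0, 1, 1])
        assert auc(np.array([0.1, 0.2, 0.8, 0.9]), labels) == 1.0
        assert auc(np.array([0.9, 0.8, 0.2, 0.1]), labels) == 0.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(8)
        n = 5000
        labels = (rng.random(n) < 0.3).astype(int)
        val = auc(rng.random(n), labels)
        P, N = labels.sum(), n - labels.sum()
        se = math.sqrt((P + N + 1) / (12 * P * N))
        assert abs(val - 0.5) < 3 * se

    def test_ties_get_half_credit(self):
        assert auc(np.zeros(4), np.array([0, 1, 0, 1])) == 0.5


class TestRebalance:
    def test_balanced_input_preserved(self):
        table = planted_feature_table(n=100, p=3, effect=1.0, skew=1.0, seed=2)
        out = rebalance(table, seed=1)
        assert out.n == 100
        assert abs(int(out.y.sum()) - 50) <= 1

    def test_skewed_input_balanced(self):
        table = planted_feature_table(n=1000, p=4, effect=1.0, skew=1 / 9, seed=3)
        out = rebalance(table, seed=1)
        assert out.n == 1000
        assert abs(int(out.y.sum()) - 500) <= 1

    def test_synthetic_minority_moments_at_small_shrink(self):
        table = planted_feature_table(n=600, p=3, effect=1.5, skew=0.25, seed=4)
        real_min = table.values.to_numpy()[table.y == 1]
        out = rebalance(table, seed=5, shrink=1e-6)
        synth = out.values.to_numpy()[out.y == 1]
        se = real_min.std(axis=0, ddof=1) / math.sqrt(len(synth))
        assert np.all(np.abs(synth.mean(axis=0) - real_min.mean(axis=0)) < 3 * se)

    def test_tiny_minority_rejected(self):
        table = planted_feature_table(n=30, p=2, effect=1.0, skew=0.5, seed=5)
        table.labels.iloc[:] = "Other"
        table.labels.iloc[0] = "lncRNA"
        with pytest.raises(ValueError, match="minority"):
            rebalance(table)


class TestCrossvalidate:
    def test_separable_data_scores_high(self):
        table = planted_feature_table(n=200, p=4, effect=6.0, skew=0.5, seed=6)
        report = crossvalidate(table, ["f01"], "NBayes", folds=5, seed=1)
        assert report.aggregate["auc"] > 0.99
        assert report.aggregate["aupr_norm"] > 0.97

    def test_permuted_labels_near_null(self):
        rng = np.random.default_rng(9)
        table = planted_feature_table(n=2000, p=3, effect=2.0, skew=0.25, seed=7)
        table.labels.iloc[:] = table.labels.iloc[rng.permutation(table.n)].to_numpy()
        report = crossvalidate(table, ["f01", "f02"], "NBayes", folds=5, seed=2)
        pi = table.y.mean()
        assert report.aggregate["auc"] == pytest.approx(0.5, abs=0.05)
        assert report.aggregate["aupr_raw"] == pytest.approx(pi, abs=0.05)
        assert report.aggregate["aupr_norm"] < 0.12

    def test_deterministic_given_seed(self, planted_table):
        a = crossvalidate(planted_table, ["f01", "f02"], "SVM", folds=5, seed=3)
        b = crossvalidate(planted_table, ["f01", "f02"], "SVM", folds=5, seed=3)
        assert a.aggregate == b.aggregate

    def test_too_many_folds_rejected(self):
        table = planted_feature_table(n=40, p=2, effect=1.0, skew=0.25, seed=8)
        with pytest.raises(ValueError, match="folds"):
            crossvalidate(table, ["f01"], "NBayes", folds=30, seed=0)


class TestRepeatedHoldout:
    def test_separable_data_perfect_with_zero_ci(self):
        table = planted_feature_table(n=500, p=3, effect=8.0, skew=1.0, seed=10)
        report = repeated_holdout(
            table, ["f01"], "NBayes", n_rep=5, per_class=40, seed=1
        )
        for metric in ("precision", "recall", "accuracy"):
            mean, half = report.holdout[metric]
            assert mean == pytest.approx(1.0)
            assert half == pytest.approx(0.0, abs=1e-12)

    def test_null_accuracy_near_half(self):
        table = planted_feature_table(n=600, p=2, effect=0.0, skew=1.0, seed=11)
        report = repeated_holdout(
            table, ["f01", "f02"], "NBayes", n_rep=5, per_class=50, seed=2
        )
        mean, half = report.holdout["accuracy"]
        assert mean == pytest.approx(0.5, abs=0.15)

    def test_deterministic_and_requires_rows(self):
        table = planted_feature_table(n=300, p=2, effect=2.0, skew=1.0, seed=12)
        a = repeated_holdout(table, ["f01"], "NBayes", n_rep=3, per_class=30, seed=4)
        b = repeated_holdout(table, ["f01"], "NBayes", n_rep=3, per_class=30, seed=4)
        assert a.holdout == b.holdout
        with pytest.raises(ValueError, match="rows"):
            repeated_holdout(table, ["f01"], "NBayes", per_class=1000)


class TestClassify:
    def test_calls_follow_threshold(self):
        train = planted_feature_table(n=200, p=3, effect=5.0, skew=0.5, seed=13)
        test = planted_feature_table(n=50, p=3, effect=5.0, skew=0.5, seed=14)
        calls = classify(test, ["f01"], train, classifier="NBayes", seed=1)
        assert (calls["lncRNA_call"] == (calls["probability"] > 0.5)).all()
        agreement = (calls["lncRNA_call"].to_numpy() == (test.y == 1)).mean()
        assert agreement > 0.95
        none_called = classify(test, ["f01"], train, classifier="NBayes",
                               threshold=1.0, seed=1)
        assert not none_called["lncRNA_call"].any()

    def test_missing_features_listed(self, planted_table):
        test = planted_table.select(["f02", "f03"])
        with pytest.raises(KeyError, match="f01"):
            classify(test, ["f01"], planted_table)
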