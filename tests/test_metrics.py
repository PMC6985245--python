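"""Selection metrics: confusion rates, ROC/AUC, clone recovery, GI, pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropsort.metrics import (
    ConfusionCounts,
    SampleComposition,
    accuracy,
    classify,
    confusion,
    dead_pass_rate,
    dead_recognition_rate,
    fpr_paper,
    growth_increase,
    growth_increase_from_recoveries,
    pooled_recovery,
    predicted_clone_recovery,
    roc_auc,
    tpr,
)

V, D = "viable", "dead"
HAND = ConfusionCounts(TP=3, FN=1, FP=2, TN=4)


def pairwise_auc(labels, scores):
    """Brute-force oracle: P(viable outscores dead), ties counting 1/2."""
    labels = np.asarray(labels)
    pos = np.asarray(scores)[labels == 1] if labels.dtype.kind != "U" else None
    y = labels == V if labels.dtype.kind == "U" else labels.astype(bool)
    pos = np.asarray(scores, float)[y]
    neg = np.asarray(scores, float)[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_predictions(self):
        labels = [V] * 5 + [D] * 5
        cc = confusion(labels, labels)
        assert (cc.TP, cc.TN, cc.FP, cc.FN) == (5, 5, 0, 0)

    def test_hand_counted_example(self):
        labels = [V, V, V, V, D, D, D, D, D, D]
        preds = [V, V, V, D, V, V, D, D, D, D]
        cc = confusion(labels, preds)
        assert (cc.TP, cc.FN, cc.FP, cc.TN) == (3, 1, 2, 4)
        assert cc.total == 10

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([V], [V, D])


class TestRates:
    def test_tpr(self):
        assert tpr(HAND) == 0.75
        assert tpr(ConfusionCounts(5, 0, 0, 0)) == 1.0
        assert tpr(ConfusionCounts(0, 0, 0, 3)) == 0.0
        with pytest.raises(ZeroDivisionError):
            tpr(ConfusionCounts(0, 2, 2, 0))

    def test_dead_recognition_and_pass(self):
        assert dead_recognition_rate(HAND) == pytest.approx(4 / 6)
        assert dead_pass_rate(HAND) == pytest.approx(2 / 6)
        assert dead_recognition_rate(ConfusionCounts(1, 0, 5, 1)) == 1.0
        assert dead_recognition_rate(ConfusionCounts(1, 5, 0, 1)) == 0.0
        with pytest.raises(ZeroDivisionError):
            dead_recognition_rate(ConfusionCounts(2, 0, 0, 2))
        assert fpr_paper is dead_recognition_rate  # documented alias

    def test_accuracy(self):
        assert accuracy(HAND) == pytest.approx(0.7)
        assert accuracy(ConfusionCounts(5, 0, 5, 0)) == 1.0
        assert accuracy(ConfusionCounts(0, 5, 0, 5)) == 0.0


class TestClassify:
    def test_strictly_above_threshold_is_viable(self):
        assert classify(0.6, 0.5) == V

    def test_equal_to_threshold_is_dead(self):
        assert classify(0.5, 0.5) == D

    def test_threshold_one_always_dead(self):
        assert all(c == D for c in classify(np.array([0.2, 0.9, 1.0]), 1.0))


class TestRocAuc:
    def test_perfect_separation(self):
        labels = [V, V, D, D]
        _, auc = roc_auc(labels, [0.9, 0.8, 0.2, 0.1])
        assert auc == 1.0

    def test_four_pair_example(self):
        # viable {0.4, 0.8} vs dead {0.1, 0.5}: 3 of 4 pairs ordered correctly
        _, auc = roc_auc([V, V, D, D], [0.4, 0.8, 0.1, 0.5])
        assert auc == pytest.approx(0.75)

    def test_label_independent_scores_near_half(self):
        # SE of AUC here is ~0.013, so 0.03 is a ~2.3 SE band
        rng = np.random.default_rng(7)
        labels = np.array([1] * 1000 + [0] * 1000)
        _, auc = roc_auc(labels, rng.uniform(size=2000))
        assert abs(auc - 0.5) < 0.03

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
            _, auc = roc_auc(labels, scores)
            assert auc == pytest.approx(pairwise_auc(labels, scores), abs=1e-12)

    def test_matches_reference_implementation(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=200)
        labels[0], labels[1] = 0, 1
        scores = rng.beta(2, 2, size=200)
        _, auc = roc_auc(labels, scores)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_curve_monotone_with_endpoints(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        curve, _ = roc_auc(labels, rng.uniform(0.01, 0.99, size=100))
        assert np.all(np.diff(curve.tpr_at) <= 0)  # non-increasing in T
        assert np.all(np.diff(curve.deadpass_at) <= 0)
        assert curve.thresholds[0] == 0.0 and curve.thresholds[-1] == 1.0
        assert (curve.tpr_at[0], curve.deadpass_at[0]) == (1.0, 1.0)
        assert (curve.tpr_at[-1], curve.deadpass_at[-1]) == (0.0, 0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([V, V], [0.1, 0.9])


class TestRecoveryAndGI:
    def test_accept_all_recovers_base_rate(self):
        assert predicted_clone_recovery(0.3, 1.0, 1.0) == pytest.approx(0.3)

    def test_perfect_classifier_recovers_everything(self):
        assert predicted_clone_recovery(0.22, 1.0, 0.0) == 1.0

    def test_worked_example(self):
        rec = predicted_clone_recovery(0.22, 0.8, 0.1)
        assert rec == pytest.approx(0.176 / (0.176 + 0.078), abs=1e-9)
        assert rec == pytest.approx(0.693, abs=5e-4)
        assert growth_increase(0.22, 0.8, 0.1) == pytest.approx(rec / 0.22)
        assert growth_increase(0.22, 0.8, 0.1) == pytest.approx(3.15, abs=5e-3)

    def test_no_classifier_baseline_gi_is_one(self):
        assert growth_increase(0.4, 1.0, 1.0) == pytest.approx(1.0)

    def test_gi_max_is_inverse_cv(self):
        assert growth_increase(0.5, 1.0, 0.0) == pytest.approx(2.0)

    def test_degenerate_inputs_flagged(self):
        with pytest.raises(ZeroDivisionError):
            predicted_clone_recovery(0.5, 0.0, 0.0)
        with pytest.raises(ZeroDivisionError):
            growth_increase(0.0, 1.0, 0.5)
        with pytest.raises(ZeroDivisionError):
            growth_increase_from_recoveries(0.5, 0.0)

    @given(
        c_v=st.floats(0.05, 0.95),
        t=st.floats(0.0, 1.0),
        dp=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_gi_identity(self, c_v, t, dp):
        """Analytic GI == recovery-ratio GI wherever both are defined."""
        if c_v * t + (1 - c_v) * dp == 0:
            return
        rec = predicted_clone_recovery(c_v, t, dp)
        assert growth_increase(c_v, t, dp) == pytest.approx(
            growth_increase_from_recoveries(rec, c_v), rel=1e-12
        )

    def test_recovery_monotone_in_operating_point(self):
        grid = np.linspace(0.01, 1.0, 12)
        for c_v in (0.1, 0.5, 0.9):
            for dp in (0.05, 0.5, 1.0):
                recs = [predicted_clone_recovery(c_v, t, dp) for t in grid]
                assert np.all(np.diff(recs) >= -1e-12)  # non-decreasing in TPR
            for t in (0.05, 0.5, 1.0):
                recs = [predicted_clone_recovery(c_v, t, dp) for dp in grid]
                assert np.all(np.diff(recs) <= 1e-12)  # non-increasing in dead-pass


class TestReportedGIFigures:
    """Reported clone-recovery ratios, rounded to two decimals as published."""

    @pytest.mark.parametrize(
        "with_,without,expected",
        [(0.73, 0.27, 2.7), (0.66, 0.22, 3.0), (0.792, 0.768, 1.03), (0.75, 0.657, 1.14)],
    )
    def test_printed_values(self, with_, without, expected):
        assert round(growth_increase_from_recoveries(with_, without), 2) == expected


class TestPooledRecovery:
    def test_two_campaign_pool(self):
        # 991 wells at 22% + 432 wells at 65.7% -> 218+284 colonies / 1423 = 35.3%
        pooled = pooled_recovery(
            [SampleComposition(991, 0.22), SampleComposition(432, 0.657)]
        )
        assert round(100 * pooled, 1) == 35.3

    def test_single_component(self):
        assert pooled_recovery([SampleComposition(200, 0.5)]) == pytest.approx(0.5)

    def test_even_split(self):
        assert pooled_recovery(
            [SampleComposition(100, 0.0), SampleComposition(100, 1.0)]
        ) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pooled_recovery([])
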