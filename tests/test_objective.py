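"""Loss functions, schedule, and evaluation metrics against hand oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from retseg.errors import ParameterError, ShapeError, UndefinedMetricError
from retseg.objective import (
    ClassBalance,
    ConfusionCounts,
    LossSchedule,
    acc_se_sp,
    beta_weight,
    confusion,
    roc_auc,
    total_loss,
    weighted_bce,
)


def brute_force_auc(scores, labels):
    """Pairwise concordance over all positive x negative pairs, ties as 1/2."""
    pos = scores[labels > 0]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestClassBalance:
    def test_alpha_is_background_fraction(self):
        b = ClassBalance.from_target(np.array([1, 0, 0, 0]))
        assert b.m == 4 and b.x_plus == 1 and b.x_minus == 3
        assert b.alpha == 0.75

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ParameterError):
            ClassBalance(m=4, x_plus=1, x_minus=1)


class TestWeightedBce:
    def test_scalar_worked_example(self):
        # m=4, y=[1,0,0,0] so alpha=0.75; hand evaluation:
        # -(1/4) [0.75 ln 0.9 + 0.25 (ln 0.9 + ln 0.8 + ln 0.7)]
        y = np.array([1.0, 0.0, 0.0, 0.0])
        yhat = np.array([0.9, 0.1, 0.2, 0.3])
        expected = -(
            0.75 * np.log(0.9) + 0.25 * (np.log(0.9) + np.log(0.8) + np.log(0.7))
        ) / 4.0
        assert weighted_bce(y, yhat) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.06258, abs=5e-5)

    def test_perfect_prediction_limit(self):
        y = np.array([1.0, 0.0, 1.0])
        assert weighted_bce(y, y) < 1e-5

    def test_balanced_classes_halve_plain_bce(self, rng):
        y = np.array([1.0, 1.0, 0.0, 0.0])
        yhat = rng.uniform(0.1, 0.9, 4)
        plain = -np.mean(y * np.log(yhat) + (1 - y) * np.log(1 - yhat))
        assert weighted_bce(y, yhat) == pytest.approx(0.5 * plain, rel=1e-10)

    @given(st.integers(0, 2**32 - 1))
    def test_loss_nonnegative(self, seed):
        r = np.random.default_rng(seed)
        y = (r.random(30) < 0.3).astype(float)
        yhat = r.random(30)
        assert weighted_bce(y, yhat) >= 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            weighted_bce(np.zeros(3), np.zeros(4))


class TestSchedule:
    @pytest.mark.parametrize(
        "epoch,total,expected", [(0, 500, 1.0), (500, 500, 0.0), (250, 500, 0.5)]
    )
    def test_beta_values(self, epoch, total, expected):
        assert beta_weight(LossSchedule(epoch, total)) == expected

    def test_epoch_beyond_total_rejected(self):
        with pytest.raises(ParameterError):
            LossSchedule(501, 500)

    def test_beta_affine_decreasing(self):
        betas = [beta_weight(LossSchedule(e, 100)) for e in range(101)]
        diffs = np.diff(betas)
        assert np.allclose(diffs, diffs[0]) and diffs[0] < 0


class TestTotalLoss:
    def test_beta_zero_keeps_main_loss_by_default(self):
        assert total_loss(1.0, 2.0, 3.0, 4.0, beta=0.0) == 4.0

    def test_beta_zero_beta_all_mode_vanishes(self):
        assert total_loss(1.0, 2.0, 3.0, 4.0, beta=0.0, beta_all=True) == 0.0

    def test_beta_one_equal_components(self):
        assert total_loss(1.0, 1.0, 1.0, 1.0, beta=1.0) == 4.0
        assert total_loss(1.0, 1.0, 1.0, 1.0, beta=1.0, beta_all=True) == 4.0

    def test_monotone_in_components(self):
        base = total_loss(1.0, 1.0, 1.0, 1.0, beta=0.5)
        assert total_loss(2.0, 1.0, 1.0, 1.0, beta=0.5) >= base
        assert total_loss(1.0, 1.0, 1.0, 2.0, beta=0.5) >= base

    def test_negative_component_rejected(self):
        with pytest.raises(ParameterError):
            total_loss(-0.1, 0.0, 0.0, 0.0, beta=0.5)


class TestConfusion:
    def test_toy_counts(self):
        truth = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        pred = np.array([1, 1, 0, 1, 0, 0, 0, 0, 0, 0])
        c = confusion(pred, truth)
        assert (c.tp, c.fn, c.fp, c.tn) == (2, 1, 1, 6)

    def test_perfect_and_inverted(self):
        truth = np.array([[1, 0], [0, 1]])
        c = confusion(truth, truth)
        assert c.fp == 0 and c.fn == 0
        c = confusion(1 - truth, truth)
        assert c.tp == 0 and c.tn == 0

    def test_mask_restriction(self):
        truth = np.array([[1, 0], [1, 0]])
        pred = np.array([[1, 1], [0, 0]])
        mask = np.array([[1, 1], [0, 0]])
        c = confusion(pred, truth, mask)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 0, 0)


class TestAccSeSp:
    def test_all_correct(self):
        assert acc_se_sp(ConfusionCounts(5, 5, 0, 0)) == (1.0, 1.0, 1.0)

    def test_toy_values(self):
        acc, se, sp = acc_se_sp(ConfusionCounts(tp=2, tn=6, fp=1, fn=1))
        assert acc == pytest.approx(0.8)
        assert se == pytest.approx(2 / 3)
        assert sp == pytest.approx(6 / 7)

    def test_sensitivity_from_counts(self):
        _, se, _ = acc_se_sp(ConfusionCounts(tp=8, tn=0, fp=1, fn=2))
        assert se == pytest.approx(0.8)

    def test_undefined_metrics_reported_absent(self):
        acc, se, sp = acc_se_sp(ConfusionCounts(tp=0, tn=4, fp=1, fn=0))
        assert se is None and sp is not None
        with pytest.raises(UndefinedMetricError):
            acc_se_sp(ConfusionCounts(0, 0, 0, 0))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        truth = np.array([1, 1, 0, 0])
        _, auc = roc_auc(scores, truth)
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        _, auc = roc_auc(np.full(10, 0.5), np.array([1] * 4 + [0] * 6))
        assert auc == pytest.approx(0.5)

    def test_four_point_example(self):
        _, auc = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(0.75)

    def test_curve_endpoints(self):
        curve, _ = roc_auc(np.array([0.2, 0.7, 0.5]), np.array([0, 1, 1]))
        assert curve[0].tolist() == [0.0, 0.0]
        assert curve[-1].tolist() == [1.0, 1.0]

    @given(st.integers(0, 2**32 - 1))
    def test_matches_pairwise_concordance(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(10, 200))
        # quantized scores generate ties, exercising the ties-as-half rule
        scores = np.round(r.random(n), 2)
        truth = (r.random(n) < 0.4).astype(int)
        if truth.sum() in (0, n):
            truth[0] = 1 - truth[0]
        _, auc = roc_auc(scores, truth)
        assert auc == pytest.approx(brute_force_auc(scores, truth), abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_mask_restricts_pixels(self):
        scores = np.array([[0.9, 0.1], [0.5, 0.5]])
        truth = np.array([[1, 0], [1, 0]])
        mask = np.array([[1, 1], [0, 0]])
        _, auc = roc_auc(scores, truth, mask)
        assert auc == 1.0
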