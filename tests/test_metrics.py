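import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfseg3d.metrics import (
    BootstrapResult,
    ConfusionCounts,
    UndefinedStatisticError,
    balanced_accuracy,
    bootstrap_ci,
    confusion,
    mcc,
    optimal_threshold,
    paired_difference_ci,
    roc_curve,
)


# ------------------------------------------------------------------ confusion


def test_confusion_hand_count():
    region = np.ones((10, 1, 1), bool)
    truth = np.zeros((10, 1, 1), bool)
    truth[:3] = True
    pred = np.zeros((10, 1, 1), bool)
    pred[1:3] = True  # covers 2 of the 3 truth voxels
    pred[5] = True  # one false positive
    c = confusion(pred, truth, region)
    assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 6)


def test_confusion_perfect_and_inverted():
    region = np.ones((4, 4, 4), bool)
    truth = np.zeros((4, 4, 4), bool)
    truth[0] = True
    perfect = confusion(truth, truth, region)
    assert perfect.fp == perfect.fn == 0
    inverted = confusion(~truth, truth, region)
    assert inverted.tp == inverted.tn == 0


def test_confusion_restricted_to_region():
    region = np.zeros((4, 4, 4), bool)
    region[0] = True
    truth = np.ones((4, 4, 4), bool)
    pred = np.zeros((4, 4, 4), bool)
    c = confusion(pred, truth, region)
    assert c.total == 16


def test_confusion_empty_region_raises():
    z = np.zeros((2, 2, 2), bool)
    with pytest.raises(ValueError):
        confusion(z, z, z)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ConfusionCounts(-1, 0, 0, 0)


# ------------------------------------------------------------------------ mcc


def test_mcc_reference_values():
    assert mcc(ConfusionCounts(tp=10, fp=0, fn=0, tn=10)) == pytest.approx(1.0)
    assert mcc(ConfusionCounts(tp=25, fp=25, fn=25, tn=25)) == pytest.approx(0.0)
    # direct formula evaluation as the independent oracle:
    # (45*40 - 10*5) / sqrt(55 * 50 * 50 * 45) = 0.70352...
    assert mcc(ConfusionCounts(tp=45, fp=10, fn=5, tn=40)) == pytest.approx(
        0.7035, abs=1e-4
    )


def test_mcc_degenerate_denominator_is_zero():
    assert mcc(ConfusionCounts(tp=0, fp=0, fn=5, tn=5)) == 0.0
    assert mcc(ConfusionCounts(tp=5, fp=5, fn=0, tn=0)) == 0.0


@settings(max_examples=100, deadline=None)
@given(
    tp=st.integers(0, 50), fp=st.integers(0, 50),
    fn=st.integers(0, 50), tn=st.integers(0, 50),
)
def test_mcc_class_swap_and_inversion_symmetries(tp, fp, fn, tn):
    c = ConfusionCounts(tp, fp, fn, tn)
    swapped = ConfusionCounts(tp=tn, fp=fn, fn=fp, tn=tp)  # swap classes
    inverted = ConfusionCounts(tp=fp, fp=tp, fn=tn, tn=fn)  # invert predictions
    assert mcc(c) == pytest.approx(mcc(swapped), abs=1e-12)
    assert mcc(c) == pytest.approx(-mcc(inverted), abs=1e-12)


# ---------------------------------------------------------- balanced accuracy


def test_balanced_accuracy_values():
    assert balanced_accuracy(ConfusionCounts(10, 0, 0, 10)) == 1.0
    # all-positive prediction, half the voxels truly positive
    assert balanced_accuracy(ConfusionCounts(tp=10, fp=10, fn=0, tn=0)) == 0.5
    assert balanced_accuracy(ConfusionCounts(tp=45, fp=10, fn=5, tn=40)) == pytest.approx(
        0.85
    )


# ------------------------------------------------------------------------ roc


def _pairwise_auc(scores, truth):
    """Brute-force concordance oracle: (concordant + 0.5 ties) / (n+ * n-)."""
    pos = scores[truth]
    neg = scores[~truth]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_roc_perfect_and_chance():
    truth = np.array([True] * 5 + [False] * 5)
    perfect = roc_curve(np.r_[np.ones(5), np.zeros(5)], truth)
    assert perfect.auc == pytest.approx(1.0)
    chance = roc_curve(np.full(10, 0.5), truth)
    assert chance.auc == pytest.approx(0.5)


def test_roc_endpoints_and_monotonicity(rng):
    scores = rng.normal(size=60)
    truth = rng.random(60) < 0.4
    truth[0], truth[1] = True, False
    roc = roc_curve(scores, truth)
    assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
    assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
    assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()


def test_roc_auc_equals_pairwise_concordance_oracle(rng):
    for trial in range(50):
        n = int(rng.integers(8, 60))
        scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)  # force ties
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            continue
        assert roc_curve(scores, truth).auc == pytest.approx(
            _pairwise_auc(scores, truth), abs=1e-12
        )


def test_roc_single_class_raises():
    with pytest.raises(ValueError):
        roc_curve(np.arange(5.0), np.ones(5, bool))


# ---------------------------------------------------------- optimal threshold


def _exhaustive_best_balanced_accuracy(scores, truth):
    best_val, best_thr = -1.0, None
    for t in np.unique(scores):
        pred = scores >= t
        tp = (pred & truth).sum()
        fp = (pred & ~truth).sum()
        fn = (~pred & truth).sum()
        tn = (~pred & ~truth).sum()
        sens = tp / max(tp + fn, 1)
        spec = tn / max(tn + fp, 1)
        val = (sens + spec) / 2
        if val > best_val - 1e-12:
            if val > best_val + 1e-12 or (best_thr is not None and t < best_thr):
                best_val, best_thr = max(val, best_val), t
    return best_thr, best_val


def test_optimal_threshold_matches_exhaustive_scan(rng):
    for trial in range(30):
        n = int(rng.integers(8, 40))
        scores = rng.choice(np.linspace(0, 1, 7), size=n)
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            continue
        thr, val = optimal_threshold(scores, truth)
        thr_o, val_o = _exhaustive_best_balanced_accuracy(scores, truth)
        assert val == pytest.approx(val_o, abs=1e-12)
        assert thr == pytest.approx(thr_o, abs=1e-12)  # tie -> lower threshold


def test_optimal_threshold_identical_scores_gives_half():
    truth = np.array([True, False, True, False])
    thr, val = optimal_threshold(np.full(4, 0.3), truth)
    assert val == pytest.approx(0.5)


def test_optimal_threshold_separable_returns_lower_boundary():
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    truth = np.array([True, True, False, False])
    thr, val = optimal_threshold(scores, truth)
    assert val == pytest.approx(1.0)
    assert thr == pytest.approx(0.8)  # the lower edge of the separating gap


# ------------------------------------------------------------------ bootstrap


def test_bootstrap_constant_statistic_degenerate_ci():
    res = bootstrap_ci(list(range(10)), lambda cases: 3.14, n_resamples=200, seed=0)
    assert res.ci_low == res.ci_high == res.point == 3.14


def test_bootstrap_same_seed_is_identical(rng):
    data = list(rng.normal(size=20))
    a = bootstrap_ci(data, lambda c: float(np.mean(c)), n_resamples=500, seed=42)
    b = bootstrap_ci(data, lambda c: float(np.mean(c)), n_resamples=500, seed=42)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


def test_bootstrap_needs_two_cases():
    with pytest.raises(ValueError):
        bootstrap_ci([1.0], lambda c: 0.0, n_resamples=10, seed=0)


def test_bootstrap_redraws_undefined_resamples(rng):
    # statistic undefined when a resample misses class "1"
    data = [0, 0, 0, 0, 1]

    def stat(cases):
        if 1 not in cases:
            raise UndefinedStatisticError()
        return float(np.mean(cases))

    res = bootstrap_ci(data, stat, n_resamples=300, seed=3)
    assert np.isfinite(res.ci_low) and np.isfinite(res.ci_high)


def test_bootstrap_gives_up_when_resamples_never_defined():
    calls = {"n": 0}

    def stat(cases):
        calls["n"] += 1
        if calls["n"] == 1:
            return 0.0  # defined on the original sample
        raise UndefinedStatisticError()

    with pytest.raises(RuntimeError, match="gave up"):
        bootstrap_ci([1, 2, 3], stat, n_resamples=5, seed=0)


def test_bootstrap_statistic_undefined_on_original_sample():
    def stat(cases):
        raise UndefinedStatisticError()

    with pytest.raises(ValueError):
        bootstrap_ci([1, 2, 3], stat, n_resamples=5, seed=0)


def test_paired_difference_identical_methods_contains_zero(rng):
    data = list(rng.normal(size=15))
    stat = lambda c: float(np.mean(c))
    res = paired_difference_ci(data, stat, stat, n_resamples=400, seed=1)
    assert res.ci_low <= 0.0 <= res.ci_high
    assert res.significant is False


def test_paired_difference_constant_offset(rng):
    data = list(rng.normal(size=15))
    stat_a = lambda c: float(np.mean(c)) + 1.0
    stat_b = lambda c: float(np.mean(c))
    res = paired_difference_ci(data, stat_a, stat_b, n_resamples=400, seed=1)
    assert res.point == pytest.approx(1.0)
    assert res.ci_low == pytest.approx(1.0) and res.ci_high == pytest.approx(1.0)
    assert res.significant is True
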