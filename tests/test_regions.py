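import numpy as np
import pytest
from scipy import ndimage

from perfseg3d.regions import case_hu_summary, classify_case, match_regions
from perfseg3d.volio import BinaryMask, CTVolume, ProbabilityMap


def _mask(arr):
    return BinaryMask(np.asarray(arr, bool), (1, 1, 1))


def _blob(shape, center, r):
    out = np.zeros(shape, bool)
    sl = tuple(slice(max(c - r, 0), c + r + 1) for c in center)
    out[sl] = True
    return out


SHAPE = (24, 24, 24)
FULL = _mask(np.ones(SHAPE, bool))


def test_exact_match_is_one_true_positive():
    blob = _blob(SHAPE, (6, 6, 6), 2)
    res = match_regions(_mask(blob), _mask(blob), FULL)
    assert (res.n_true_positive_regions, res.n_false_positive_regions,
            res.n_false_negative_regions) == (1, 0, 0)


def test_multiple_overlapping_predictions_count_as_one_tp():
    truth = _blob(SHAPE, (10, 10, 10), 4)
    pred = _blob(SHAPE, (8, 10, 10), 1) | _blob(SHAPE, (13, 10, 10), 1)
    pred |= _blob(SHAPE, (20, 20, 20), 1)  # one stray blob
    res = match_regions(_mask(pred), _mask(truth), FULL)
    assert (res.n_true_positive_regions, res.n_false_positive_regions,
            res.n_false_negative_regions) == (1, 1, 0)


def test_empty_prediction_counts_all_truth_as_false_negative():
    truth = _blob(SHAPE, (5, 5, 5), 2) | _blob(SHAPE, (18, 18, 18), 2)
    res = match_regions(_mask(np.zeros(SHAPE)), _mask(truth), FULL)
    assert (res.n_true_positive_regions, res.n_false_positive_regions,
            res.n_false_negative_regions) == (0, 0, 2)


def test_predictions_outside_lung_are_ignored():
    lung = _mask(_blob(SHAPE, (8, 8, 8), 6))
    pred = _blob(SHAPE, (20, 20, 20), 2)  # entirely outside the lung
    truth = np.zeros(SHAPE, bool)
    res = match_regions(_mask(pred), _mask(truth), lung)
    assert res.n_false_positive_regions == 0


def test_tp_plus_fn_equals_manual_component_count(rng):
    truth = rng.random(SHAPE) < 0.02
    pred = rng.random(SHAPE) < 0.02
    res = match_regions(_mask(pred), _mask(truth), FULL)
    _, n_manual = ndimage.label(truth, structure=np.ones((3, 3, 3), bool))
    assert res.n_true_positive_regions + res.n_false_negative_regions == n_manual
    assert res.n_manual_regions == n_manual


def test_dilating_prediction_never_decreases_tp_or_increases_fn(rng):
    truth = rng.random(SHAPE) < 0.03
    pred = rng.random(SHAPE) < 0.01
    base = match_regions(_mask(pred), _mask(truth), FULL)
    dilated = ndimage.binary_dilation(pred, iterations=2)
    grown = match_regions(_mask(dilated), _mask(truth), FULL)
    assert grown.n_true_positive_regions >= base.n_true_positive_regions
    assert grown.n_false_negative_regions <= base.n_false_negative_regions


def test_region_volumes_in_ml():
    truth = np.zeros(SHAPE, bool)
    truth[:2, :5, :5] = True  # 50 voxels
    spacing = (2.0, 2.0, 2.0)
    res = match_regions(
        BinaryMask(np.zeros(SHAPE, bool), spacing),
        BinaryMask(truth, spacing),
        BinaryMask(np.ones(SHAPE, bool), spacing),
    )
    assert res.manual_region_volumes_ml == [pytest.approx(50 * 8.0 / 1000.0)]


def test_classify_case_calls():
    lung = FULL
    zero = ProbabilityMap(np.zeros(SHAPE), (1, 1, 1))
    call, mean = classify_case(zero, lung)
    assert call is False and mean == 0.0
    uniform = ProbabilityMap(np.full(SHAPE, 0.6), (1, 1, 1))
    call, mean = classify_case(uniform, lung, cutoff=0.55)
    assert call is True and mean == pytest.approx(0.6)
    # inclusive rule at the cutoff (0.5 is exactly representable, so the
    # lung mean equals the cutoff bit for bit)
    boundary = ProbabilityMap(np.full(SHAPE, 0.5), (1, 1, 1))
    call, _ = classify_case(boundary, lung, cutoff=0.5)
    assert call is True


def test_classify_case_empty_lung_raises():
    pmap = ProbabilityMap(np.zeros(SHAPE), (1, 1, 1))
    with pytest.raises(ValueError):
        classify_case(pmap, _mask(np.zeros(SHAPE)), 0.55)


def test_case_hu_summary_readings():
    lung = FULL
    high = CTVolume(np.full(SHAPE, -700.0), (1, 1, 1))
    s = case_hu_summary(high, lung, -850.0)
    assert s.fraction_below == 0.0 and s.mean_hu_below is None

    low = CTVolume(np.full(SHAPE, -900.0), (1, 1, 1))
    s = case_hu_summary(low, lung, -850.0)
    assert s.fraction_below == 1.0 and s.mean_hu_below == pytest.approx(-900.0)

    half = np.full(SHAPE, -700.0)
    half[:12] = -900.0
    s = case_hu_summary(CTVolume(half, (1, 1, 1)), lung, -850.0)
    assert s.fraction_below == pytest.approx(0.5)
    assert s.mean_hu_below == pytest.approx(-900.0)
    assert s.mean_lung_hu == pytest.approx(-800.0)
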