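import dataclasses

import numpy as np
import pytest

from perfseg3d.model import (
    EarlyStopping,
    TrainConfig,
    build_unet,
    dice_loss,
    predict_dense,
    predict_volume,
    train,
)
from perfseg3d.model import _dice_loss_and_grad
from perfseg3d.nn.network import (
    ShapeTraceError,
    UNet3D,
    UNetConfig,
    UNetConfigError,
    sigmoid,
    trace_output_size,
)
from perfseg3d.phantom import PhantomConfig, generate_case
from perfseg3d.experiment import prepare_case
from perfseg3d.volio import BinaryMask, CTVolume


REF = UNetConfig()  # reference margin-30 architecture


# ---------------------------------------------------------------- shape trace


def test_reference_network_maps_92_to_32():
    assert trace_output_size(REF, 92) == 32


def test_shrinkage_is_input_size_independent():
    for n in (68, 76, 92, 100):
        assert n - trace_output_size(REF, n) == 60


def test_inadmissible_sizes_raise():
    with pytest.raises(ShapeTraceError):
        trace_output_size(REF, 91)  # odd size hits a pooling step
    with pytest.raises(ShapeTraceError):
        trace_output_size(REF, 36)  # too small for the bottleneck


def test_margin_mismatch_names_achieved_shrinkage():
    bad = dataclasses.replace(REF, margin=25)
    with pytest.raises(UNetConfigError, match="30"):
        build_unet(bad)


def test_real_forward_matches_trace(small_unet_config):
    net = build_unet(small_unet_config, seed=0)
    n = 28  # admissible for the margin-6 experiment network
    out = net.forward(np.zeros((1, 1, n, n, n), np.float32))
    expected = trace_output_size(small_unet_config, n)
    assert out.shape == (1, 1, expected, expected, expected)
    assert n - expected == 2 * small_unet_config.margin


def test_untrained_output_is_strictly_inside_unit_interval(small_unet_config, rng):
    net = build_unet(small_unet_config, seed=1)
    x = rng.normal(size=(2, 1, 28, 28, 28)).astype(np.float32)
    p = net.predict_proba(x)
    assert (p > 0).all() and (p < 1).all()


def test_deterministic_initialization(small_unet_config):
    a = build_unet(small_unet_config, seed=9)
    b = build_unet(small_unet_config, seed=9)
    for (va, _), (vb, _) in zip(a.param_items(), b.param_items()):
        assert np.array_equal(va, vb)


def test_save_load_round_trip(tmp_path, small_unet_config, rng):
    net = build_unet(small_unet_config, seed=4)
    path = tmp_path / "model.npz"
    net.save(path)
    loaded = UNet3D.load(path)
    x = rng.normal(size=(1, 1, 28, 28, 28)).astype(np.float32)
    assert np.array_equal(net.predict_proba(x), loaded.predict_proba(x))


# ------------------------------------------------------------------ dice loss


def test_dice_loss_perfect_overlap_is_zero():
    t = (np.arange(64) % 3 == 0).astype(float).reshape(4, 4, 4)
    assert dice_loss(t, t, smooth=1.0) == pytest.approx(0.0, abs=1e-3)


def test_dice_loss_disjoint_masses():
    p = np.zeros((4, 4, 4))
    t = np.zeros((4, 4, 4))
    p[0] = 1.0
    t[1] = 1.0
    n = 16
    assert dice_loss(p, t, smooth=1.0) == pytest.approx(1 - 1.0 / (2 * n + 1))


def test_dice_loss_half_overlap_in_smooth_limit():
    p = np.zeros((4, 4, 4))
    t = np.zeros((4, 4, 4))
    p[:2] = 1.0
    t[1:3] = 1.0  # equal size, half overlap
    assert dice_loss(p, t, smooth=1e-9) == pytest.approx(0.5, abs=1e-6)


def test_dice_loss_symmetric_for_binary_masks(rng):
    p = (rng.random((5, 5, 5)) < 0.4).astype(float)
    t = (rng.random((5, 5, 5)) < 0.4).astype(float)
    assert dice_loss(p, t) == pytest.approx(dice_loss(t, p))


def test_dice_loss_flipping_an_agreeing_voxel_never_decreases_loss(rng):
    p = (rng.random((4, 4, 4)) < 0.5).astype(float)
    t = p.copy()
    base = dice_loss(p, t, smooth=1e-9)
    agree = np.argwhere(p == t)
    i = tuple(agree[0])
    q = p.copy()
    q[i] = 1 - q[i]
    assert dice_loss(q, t, smooth=1e-9) >= base


def test_dice_loss_shape_mismatch():
    with pytest.raises(ValueError):
        dice_loss(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


def test_dice_gradient_matches_finite_differences(rng):
    p = rng.random((3, 3, 3)).astype(np.float64)
    t = (rng.random((3, 3, 3)) < 0.5).astype(np.float64)
    _, grad = _dice_loss_and_grad(p, t, smooth=1.0)
    eps = 1e-5
    for idx in [(0, 0, 0), (1, 2, 1), (2, 2, 2)]:
        q = p.copy()
        q[idx] += eps
        up = dice_loss(q, t, 1.0)
        q[idx] -= 2 * eps
        dn = dice_loss(q, t, 1.0)
        assert grad[idx] == pytest.approx((up - dn) / (2 * eps), abs=1e-5)


# ------------------------------------------------------------------- training


def _tiny_cases(n, seed0=400, positive=True):
    cfg = PhantomConfig(hu_noise_sd=10.0, artifact_streaks=0)
    return [
        prepare_case(
            generate_case(dataclasses.replace(cfg, seed=seed0 + i), positive), 2.0
        )
        for i in range(n)
    ]


@pytest.fixture(scope="module")
def tiny_training_setup(small_unet_config):
    cases = _tiny_cases(3)
    tcfg = TrainConfig(
        learning_rate=5e-3,
        batch_size=8,
        max_epochs=3,
        patience=3,
        patch=16,
        margin=6,
        patches_per_case=12,
        lesion_oversample=0.5,
        seed=0,
    )
    return cases, tcfg


def test_training_reduces_loss_and_is_deterministic(tiny_training_setup, small_unet_config):
    cases, tcfg = tiny_training_setup
    net_a = build_unet(small_unet_config, seed=2)
    hist_a = train(net_a, cases[:2], cases[2:], tcfg)
    assert hist_a.train_loss[-1] < hist_a.train_loss[0]
    net_b = build_unet(small_unet_config, seed=2)
    hist_b = train(net_b, cases[:2], cases[2:], tcfg)
    assert hist_a.train_loss[0] == pytest.approx(hist_b.train_loss[0], rel=1e-6)


def test_training_requires_cases(small_unet_config):
    net = build_unet(small_unet_config, seed=0)
    with pytest.raises(ValueError):
        train(net, [], [], TrainConfig(patch=16, margin=6))


def test_early_stopping_stops_patience_epochs_after_best():
    stopper = EarlyStopping(patience=3)
    values = [0.1, 0.5, 0.4, 0.4, 0.4, 0.9]  # never improves after epoch 1
    stopped_at = None
    for epoch, v in enumerate(values):
        if stopper.update(v, epoch):
            stopped_at = epoch
            break
    assert stopped_at == 4  # best at epoch 1, stop at 1 + 3
    assert stopper.best_epoch == 1


# ----------------------------------------------------------------- prediction


def test_predict_on_empty_lung_is_all_zero(small_unet_config):
    net = build_unet(small_unet_config, seed=0)
    vol = CTVolume(np.zeros((32, 32, 32), np.float32), (1, 1, 1))
    lung = BinaryMask(np.zeros((32, 32, 32), bool), (1, 1, 1))
    pmap = predict_volume(net, vol, lung, patch=16)
    assert pmap.data.sum() == 0


def test_predict_margin_mismatch_raises(small_unet_config):
    net = build_unet(small_unet_config, seed=0)
    vol = CTVolume(np.zeros((32, 32, 32), np.float32), (1, 1, 1))
    lung = BinaryMask(np.ones((32, 32, 32), bool), (1, 1, 1))
    with pytest.raises(UNetConfigError):
        predict_volume(net, vol, lung, patch=16, margin=30)


def test_tiled_prediction_equals_dense(prepared_positive, small_unet_config):
    net = build_unet(small_unet_config, seed=3)
    tiled = predict_volume(
        net, prepared_positive.volume, prepared_positive.lung_mask, patch=16
    )
    dense = predict_dense(net, prepared_positive.volume, prepared_positive.lung_mask)
    assert np.abs(tiled.data - dense.data).max() <= 1e-5
    assert tiled.data.min() >= 0.0 and tiled.data.max() <= 1.0


def test_briefly_trained_net_separates_clean_high_contrast_phantoms(small_unet_config):
    # learnability: no noise, no artifacts, large contrast
    cfg = PhantomConfig(
        hu_noise_sd=0.0, artifact_streaks=0, hypoperfused_hu=-950.0,
        normal_parenchyma_hu=-700.0,
    )
    cases = [
        prepare_case(generate_case(dataclasses.replace(cfg, seed=500 + i), True), 2.0)
        for i in range(4)
    ]
    net = build_unet(small_unet_config, seed=0)
    tcfg = TrainConfig(
        learning_rate=7e-3, batch_size=8, max_epochs=4, patience=4,
        patch=16, margin=6, patches_per_case=24, lesion_oversample=0.5,
        input_clip=2.0, lr_final_fraction=0.1, seed=0,
    )
    train(net, cases[:2], cases[2:3], tcfg)
    test_case = cases[3]
    pmap = predict_volume(net, test_case.volume, test_case.lung_mask, patch=16,
                          input_clip=2.0)
    lung = test_case.lung_mask.data
    from perfseg3d.metrics import roc_curve

    roc = roc_curve(pmap.data[lung], test_case.lesion_mask.data[lung])
    assert roc.auc > 0.95
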