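import numpy as np
import pytest

from perfseg3d.patching import (
    PatchPlan,
    extract_window,
    plan_inference_tiles,
    sample_training_patches,
    stitch,
)
from perfseg3d.volio import BinaryMask, CTVolume


def _grid(shape=(64, 64, 64)):
    vol = CTVolume(np.zeros(shape, np.float32), (1, 1, 1))
    full = BinaryMask(np.ones(shape, bool), (1, 1, 1))
    empty_label = BinaryMask(np.zeros(shape, bool), (1, 1, 1))
    return vol, full, empty_label


def test_window_side_is_patch_plus_two_margins():
    vol, full, label = _grid()
    samples = sample_training_patches(vol, full, label, patch=32, margin=30, n=2, seed=0)
    for win, lab, lung in samples:
        assert win.shape == (92, 92, 92)
        assert lab.shape == (32, 32, 32)


def test_full_lung_never_rejects():
    vol, full, label = _grid((40, 40, 40))
    samples = sample_training_patches(vol, full, label, patch=16, margin=5, n=10, seed=1)
    assert len(samples) == 10


def test_octant_lung_restricts_placements(rng):
    shape = (48, 48, 48)
    vol = CTVolume(rng.normal(size=shape).astype(np.float32), (1, 1, 1))
    lung = np.zeros(shape, bool)
    lung[:20, :20, :20] = True  # one octant
    label = BinaryMask(np.zeros(shape, bool), (1, 1, 1))
    samples = sample_training_patches(
        vol, BinaryMask(lung, (1, 1, 1)), label, patch=16, margin=4, n=25, seed=3
    )
    # brute-force: every returned lung patch must intersect the octant
    for _, _, lung_patch in samples:
        assert lung_patch.any()


def test_lesion_oversampling_guarantees_lesion_content(rng):
    shape = (48, 48, 48)
    vol = CTVolume(rng.normal(size=shape).astype(np.float32), (1, 1, 1))
    lung = BinaryMask(np.ones(shape, bool), (1, 1, 1))
    label = np.zeros(shape, bool)
    label[10:14, 10:14, 10:14] = True
    samples = sample_training_patches(
        vol, lung, BinaryMask(label, (1, 1, 1)), patch=16, margin=4, n=10, seed=5,
        lesion_oversample=0.5,
    )
    n_with_lesion = sum(lab.any() for _, lab, _ in samples)
    assert n_with_lesion >= 5


def test_empty_lung_raises():
    vol, _, label = _grid((32, 32, 32))
    empty = BinaryMask(np.zeros((32, 32, 32), bool), (1, 1, 1))
    with pytest.raises(ValueError, match="lung"):
        sample_training_patches(vol, empty, label, patch=16, margin=4, n=1, seed=0)


def test_plan_counts_full_volume():
    _, full, _ = _grid((64, 64, 64))
    plan = plan_inference_tiles((64, 64, 64), full, patch=32, margin=30)
    assert len(plan.placements) == 8  # 2 x 2 x 2 grid


def test_plan_clips_edge_tiles():
    _, full, _ = _grid((33, 32, 32))
    full = BinaryMask(np.ones((33, 32, 32), bool), (1, 1, 1))
    plan = plan_inference_tiles((33, 32, 32), full, patch=32, margin=30)
    starts0 = sorted({p[0] for p in plan.placements})
    assert starts0 == [0, 32]  # two placements on axis 0, second clipped to 1


def test_plan_empty_lung_gives_no_placements():
    empty = BinaryMask(np.zeros((32, 32, 32), bool), (1, 1, 1))
    plan = plan_inference_tiles((32, 32, 32), empty, patch=16, margin=4)
    assert plan.placements == ()


def test_tiling_is_a_partition(positive_case):
    lung = positive_case.lung_mask
    plan = plan_inference_tiles(lung.shape, lung, patch=16, margin=6)
    painted = np.zeros(lung.shape, np.int32)
    for start in plan.placements:
        sl = tuple(slice(lo, hi) for lo, hi in plan.tile_extent(start))
        painted[sl] += 1
    assert painted.max() == 1  # no voxel written twice
    assert (painted[lung.data] == 1).all()  # every lung voxel covered once


def test_stitch_constant_half():
    full = BinaryMask(np.ones((32, 32, 32), bool), (1, 1, 1))
    plan = plan_inference_tiles((32, 32, 32), full, patch=16, margin=4)
    outs = [np.full((16, 16, 16), 0.5, np.float32) for _ in plan.placements]
    pmap = stitch(plan, outs)
    assert np.allclose(pmap.data, 0.5)


def test_stitch_reproduces_index_function():
    shape = (32, 32, 32)
    full = BinaryMask(np.ones(shape, bool), (1, 1, 1))
    plan = plan_inference_tiles(shape, full, patch=16, margin=4)
    idx = np.arange(np.prod(shape), dtype=np.float64).reshape(shape)
    f = idx / idx.max()  # known function of the voxel index
    outs = []
    for start in plan.placements:
        sl = tuple(slice(lo, hi) for lo, hi in plan.tile_extent(start))
        outs.append(f[sl])
    pmap = stitch(plan, outs)
    assert np.array_equal(pmap.data, f)


def test_stitch_shape_mismatch_raises():
    full = BinaryMask(np.ones((32, 32, 32), bool), (1, 1, 1))
    plan = plan_inference_tiles((32, 32, 32), full, patch=16, margin=4)
    outs = [np.zeros((8, 8, 8), np.float32) for _ in plan.placements]
    with pytest.raises(ValueError):
        stitch(plan, outs)
    with pytest.raises(ValueError):
        stitch(plan, outs[:-1])


def test_extract_window_pads_by_edge_replication():
    data = np.arange(27, dtype=np.float32).reshape(3, 3, 3)
    win = extract_window(data, (0, 0, 0), size=3, margin=1)
    assert win.shape == (5, 5, 5)
    assert win[0, 1, 1] == data[0, 0, 0]  # replicated edge
    assert np.array_equal(win[1:4, 1:4, 1:4], data)


def test_plan_json_round_trip():
    full = BinaryMask(np.ones((32, 32, 32), bool), (1, 1, 1))
    plan = plan_inference_tiles((32, 32, 32), full, patch=16, margin=4)
    assert PatchPlan.from_json(plan.to_json()) == plan
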