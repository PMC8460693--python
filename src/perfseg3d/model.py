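"""Network construction, Dice-loss training and tiled volume prediction.

Training follows the patch regime: normalized input windows of side
``patch + 2*margin`` against binary label patches of side ``patch``, Adam
(default learning rate 2e-4) minimising the Dice loss with batch size 16,
early stopping when the validation metric (Dice by default, voxel accuracy
selectable) stops improving, restoring the best epoch's weights.

Prediction tiles the lung bounding box with non-overlapping label patches,
runs the network on each margin-extended window and stitches the outputs;
probabilities outside the lung are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.network import UNet3D, UNetConfig, UNetConfigError, sigmoid
from .nn.optim import Adam
from .patching import extract_window, plan_inference_tiles, sample_training_patches, stitch
from .volio import BinaryMask, CTVolume, ProbabilityMap

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "build_unet",
    "dice_loss",
    "train",
    "predict_volume",
    "predict_dense",
    "EarlyStopping",
]

F32 = np.float32


def build_unet(cfg: UNetConfig | None = None, seed: int = 0) -> UNet3D:
    """Build the U-net, validating the margin contract via the shape trace."""
    return UNet3D(cfg if cfg is not None else UNetConfig(), seed=seed)


def dice_loss(pred: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> float:
    """1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s), in [0, 1]."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    inter = float((pred * target).sum())
    denom = float(pred.sum() + target.sum()) + smooth
    return 1.0 - (2.0 * inter + smooth) / denom


def _dice_loss_and_grad(p: np.ndarray, t: np.ndarray, smooth: float):
    """Loss plus its gradient with respect to the probabilities."""
    p64 = p.astype(np.float64)
    t64 = t.astype(np.float64)
    inter2 = 2.0 * float((p64 * t64).sum()) + smooth
    denom = float(p64.sum() + t64.sum()) + smooth
    loss = 1.0 - inter2 / denom
    grad = (inter2 / denom**2) - 2.0 * t64 / denom
    return loss, grad.astype(F32)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-4
    batch_size: int = 16
    max_epochs: int = 30
    patience: int = 5
    seed: int = 0
    validation_metric: str = "dice"  # "dice" | "voxel_accuracy"
    dice_smooth: float = 1.0
    patch: int = 32
    margin: int = 30
    patches_per_case: int = 32
    #: fraction of training patches required to contain lesion voxels
    #: (0 = uniform sampling over accepted candidates)
    lesion_oversample: float = 0.0
    #: epochs after which batch-norm statistics are frozen so training
    #: optimizes the inference-time network (<0 disables freezing)
    freeze_norm_after_epoch: int = 1
    #: symmetric clip applied to normalized intensities at the network input
    #: (None = no clipping; the stored normalization itself never clips)
    input_clip: float | None = None
    #: cosine learning-rate decay toward lr_final_fraction * learning_rate
    #: over max_epochs (1.0 = constant learning rate)
    lr_final_fraction: float = 1.0
    #: patches per validation case (defaults to patches_per_case)
    val_patches_per_case: int | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.validation_metric not in ("dice", "voxel_accuracy"):
            raise ValueError(f"unknown validation metric {self.validation_metric}")


@dataclass
class TrainingHistory:
    train_loss: list[float]
    val_metric: list[float]
    best_epoch: int
    stopped_epoch: int


class EarlyStopping:
    """Stop after ``patience`` epochs without improvement (higher is better);
    keeps a copy of the best state for restoration."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_value = -np.inf
        self.best_epoch = -1
        self.best_state = None
        self._since_best = 0

    def update(self, value: float, epoch: int, state=None) -> bool:
        """Record an epoch result; returns True when training should stop."""
        if value > self.best_value:
            self.best_value = value
            self.best_epoch = epoch
            self.best_state = state
            self._since_best = 0
        else:
            self._since_best += 1
        return self._since_best >= self.patience


def _collect_samples(cases, tcfg: TrainConfig, seed: int, n_per_case: int | None = None):
    windows, labels = [], []
    seeds = np.random.SeedSequence(seed).generate_state(len(cases)) % (2**31)
    for case, s in zip(cases, seeds):
        for win, lab, _ in sample_training_patches(
            case.volume,
            case.lung_mask,
            case.lesion_mask,
            patch=tcfg.patch,
            margin=tcfg.margin,
            n=n_per_case if n_per_case is not None else tcfg.patches_per_case,
            seed=int(s),
            lesion_oversample=tcfg.lesion_oversample,
        ):
            win = win.astype(F32)
            if tcfg.input_clip is not None:
                np.clip(win, -tcfg.input_clip, tcfg.input_clip, out=win)
            windows.append(win)
            labels.append(lab.astype(F32))
    return np.stack(windows)[:, None], np.stack(labels)[:, None]


def _validation_score(net: UNet3D, x: np.ndarray, t: np.ndarray, tcfg: TrainConfig) -> float:
    probs = []
    for i in range(0, len(x), tcfg.batch_size):
        probs.append(net.predict_proba(x[i : i + tcfg.batch_size]))
    p = np.concatenate(probs)
    if tcfg.validation_metric == "voxel_accuracy":
        return float(((p >= 0.5) == (t >= 0.5)).mean())
    return 1.0 - dice_loss(p, t, smooth=tcfg.dice_smooth)


def train(net: UNet3D, train_cases, val_cases, tcfg: TrainConfig):
    """Train in place; returns a :class:`TrainingHistory`.

    Cases expose ``volume`` (a normalized :class:`CTVolume`), ``lung_mask``
    and ``lesion_mask`` on one grid.  Fully deterministic under
    ``tcfg.seed``: patch sampling, shuffling and initialization all derive
    from explicit seeds.
    """
    if not train_cases or not val_cases:
        raise ValueError("need at least one training and one validation case")
    ss = np.random.SeedSequence(tcfg.seed).generate_state(3) % (2**31)
    x_train, t_train = _collect_samples(train_cases, tcfg, int(ss[0]))
    x_val, t_val = _collect_samples(
        val_cases, tcfg, int(ss[1]), n_per_case=tcfg.val_patches_per_case
    )
    rng = np.random.default_rng(int(ss[2]))

    opt = Adam(net.param_items(), lr=tcfg.learning_rate)
    stopper = EarlyStopping(tcfg.patience)
    history = TrainingHistory(train_loss=[], val_metric=[], best_epoch=-1, stopped_epoch=-1)

    n = len(x_train)
    for epoch in range(tcfg.max_epochs):
        if tcfg.freeze_norm_after_epoch >= 0:
            net.set_norm_frozen(epoch >= tcfg.freeze_norm_after_epoch)
        if tcfg.lr_final_fraction < 1.0 and tcfg.max_epochs > 1:
            frac = epoch / (tcfg.max_epochs - 1)
            lo = tcfg.lr_final_fraction
            opt.lr = tcfg.learning_rate * (
                lo + (1 - lo) * 0.5 * (1 + np.cos(np.pi * frac))
            )
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, tcfg.batch_size):
            idx = order[i : i + tcfg.batch_size]
            xb, tb = x_train[idx], t_train[idx]
            logits = net.forward(xb, train=True)
            p = sigmoid(logits)
            loss, gp = _dice_loss_and_grad(p, tb, tcfg.dice_smooth)
            glogits = gp * p * (1.0 - p)
            net.backward(glogits)
            opt.step()
            losses.append(loss)
        val = _validation_score(net, x_val, t_val, tcfg)
        history.train_loss.append(float(np.mean(losses)))
        history.val_metric.append(float(val))
        stop = stopper.update(val, epoch, state=net.copy_state())
        if stop:
            break
    if stopper.best_state is not None:
        net.load_state(stopper.best_state)
    history.best_epoch = stopper.best_epoch
    history.stopped_epoch = len(history.train_loss) - 1
    return history


def predict_volume(
    net: UNet3D,
    vol: CTVolume,
    lung: BinaryMask,
    patch: int = 32,
    margin: int | None = None,
    batch_tiles: int = 8,
    input_clip: float | None = None,
) -> ProbabilityMap:
    """Tiled inference over the lung bounding box; zero outside the lung.

    ``vol`` must already be normalized.  The requested margin must match the
    network's traced margin.  Tile starts are multiples of ``patch`` so the
    pooling grids of all tiles share one alignment (``patch`` should be a
    multiple of the network's total stride for tiling to be exactly
    equivalent to a dense pass).
    """
    if margin is None:
        margin = net.margin
    if margin != net.margin:
        raise UNetConfigError(
            f"requested margin {margin} but the network was built with {net.margin}"
        )
    if vol.shape != lung.shape:
        raise ValueError(f"grid mismatch: volume {vol.shape} vs lung {lung.shape}")
    plan = plan_inference_tiles(vol.shape, lung, patch, margin)
    if not plan.placements:
        return ProbabilityMap(np.zeros(vol.shape, F32), vol.spacing, vol.affine)
    data = np.asarray(vol.data, dtype=F32)
    if input_clip is not None:
        data = np.clip(data, -input_clip, input_clip)
    windows = np.stack(
        [extract_window(data, start, patch, margin) for start in plan.placements]
    )[:, None]
    outputs = []
    for i in range(0, len(windows), batch_tiles):
        probs = net.predict_proba(windows[i : i + batch_tiles])
        outputs.extend(probs[:, 0])
    pmap = stitch(plan, outputs, spacing=vol.spacing)
    pmap.data[~lung.data] = 0.0
    return ProbabilityMap(pmap.data, vol.spacing, vol.affine)


def predict_dense(
    net: UNet3D, vol: CTVolume, lung: BinaryMask, input_clip: float | None = None
) -> ProbabilityMap:
    """Whole-volume inference on the replication-padded volume.

    The padded side lengths must be admissible for the network.  Used as the
    correctness oracle for tiled inference and for small volumes.
    """
    m = net.margin
    data = np.asarray(vol.data, dtype=F32)
    if input_clip is not None:
        data = np.clip(data, -input_clip, input_clip)
    data = np.pad(data, m, mode="edge")
    probs = net.predict_proba(data[None, None])[0, 0]
    if probs.shape != vol.shape:  # pragma: no cover - guarded by the shape trace
        raise RuntimeError(f"dense output {probs.shape} does not match {vol.shape}")
    out = np.where(lung.data, probs, 0.0).astype(F32)
    return ProbabilityMap(out, vol.spacing, vol.affine)
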