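"""Layers with explicit forward/backward passes (float32, NCDHW layout).

Each layer caches what its backward pass needs during ``forward`` and is used
at most once per step.  Parameter gradients are written (not accumulated)
into preallocated buffers so the optimizer can hold stable references.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3d",
    "BatchNorm3d",
    "GroupNorm3d",
    "Identity",
    "ELU",
    "ConvBlock",
    "MaxPool3d",
    "LinearUpsample3d",
    "CropConcat",
]

F32 = np.float32

#: gradients smaller than this are numerically irrelevant (Adam cannot act
#: on them) but their products underflow into subnormal floats, which slow
#: x86 arithmetic by orders of magnitude in saturated networks -- flush them
GRAD_FLUSH = 1e-25


def flush_tiny(a: np.ndarray) -> np.ndarray:
    """Zero out magnitudes below GRAD_FLUSH in place."""
    np.multiply(a, np.abs(a) >= GRAD_FLUSH, out=a)
    return a


class Conv3d:
    """Valid-padding 3-D convolution.

    Two BLAS strategies, chosen per layer: one GEMM per kernel tap (good for
    mid-sized feature maps), or an explicit channels-first column matrix with
    a single GEMM (much faster when the input has one channel -- K-degenerate
    tap GEMMs amplify memory traffic -- or when feature maps are small).
    ``compute_input_grad=False`` skips the input-gradient pass; use it for
    the first layer of a network, whose input gradient is discarded.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng,
        bias: bool = True,
        compute_input_grad: bool = True,
    ):
        fan_in = in_ch * kernel**3
        std = np.sqrt(2.0 / fan_in)
        self.w = rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel, kernel)).astype(F32)
        self.b = np.zeros(out_ch, dtype=F32) if bias else None
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b) if bias else None
        self.kernel = kernel
        self.compute_input_grad = compute_input_grad
        self._x = None
        self._col = None

    def _taps(self):
        k = self.kernel
        return [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]

    def _use_col(self, out_side: int) -> bool:
        return self.w.shape[1] == 1 or out_side <= 14

    # -- column-matrix strategy -------------------------------------------

    def _forward_col(self, x, out_shape, train):
        B, C = x.shape[:2]
        Do, Ho, Wo = out_shape
        M = B * Do * Ho * Wo
        F = self.w.shape[0]
        k3 = self.kernel**3
        xc = np.ascontiguousarray(np.moveaxis(x, 1, 0))  # (C, B, D, H, W)
        col = np.empty((k3 * C, M), dtype=F32)
        for t, (i, j, l) in enumerate(self._taps()):
            col[t * C : (t + 1) * C] = xc[
                :, :, i : i + Do, j : j + Ho, l : l + Wo
            ].reshape(C, M)
        w2 = self.w.transpose(0, 2, 3, 4, 1).reshape(F, k3 * C)
        y = w2 @ col  # (F, M)
        self._col = col if train else None
        return np.moveaxis(y.reshape(F, B, Do, Ho, Wo), 0, 1)

    def _backward_col(self, gy):
        x = self._x
        B, C, D, H, W = x.shape
        F = self.w.shape[0]
        Do, Ho, Wo = gy.shape[2:]
        M = B * Do * Ho * Wo
        k3 = self.kernel**3
        gy2 = np.ascontiguousarray(np.moveaxis(gy, 1, 0)).reshape(F, M)
        gw2 = gy2 @ self._col.T  # (F, k3*C)
        self.gw[...] = gw2.reshape(F, *([self.kernel] * 3), C).transpose(0, 4, 1, 2, 3)
        if not self.compute_input_grad:
            return None
        w2 = self.w.transpose(0, 2, 3, 4, 1).reshape(F, k3 * C)
        gcol = w2.T @ gy2  # (k3*C, M)
        gxc = np.zeros((C, B, D, H, W), dtype=F32)
        for t, (i, j, l) in enumerate(self._taps()):
            gxc[:, :, i : i + Do, j : j + Ho, l : l + Wo] += gcol[
                t * C : (t + 1) * C
            ].reshape(C, B, Do, Ho, Wo)
        return np.ascontiguousarray(np.moveaxis(gxc, 0, 1))

    # -- per-tap strategy ---------------------------------------------------

    def _forward_taps(self, x, out_shape):
        Do, Ho, Wo = out_shape
        acc = None
        for i, j, l in self._taps():
            xs = x[:, :, i : i + Do, j : j + Ho, l : l + Wo]
            # (F, C) x (B, C, d, h, w) -> (F, B, d, h, w)
            t = np.tensordot(self.w[:, :, i, j, l], xs, axes=([1], [1]))
            acc = t if acc is None else acc + t
        return np.moveaxis(acc, 0, 1)

    def _backward_taps(self, gy):
        x = self._x
        B, C, D, H, W = x.shape
        Do, Ho, Wo = gy.shape[2:]
        gx = (
            np.zeros((C, B, D, H, W), dtype=F32) if self.compute_input_grad else None
        )
        for i, j, l in self._taps():
            xs = x[:, :, i : i + Do, j : j + Ho, l : l + Wo]
            self.gw[:, :, i, j, l] = np.tensordot(
                gy, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4])
            )
            if gx is not None:
                # (F, C)^T x (B, F, d, h, w) -> (C, B, d, h, w)
                gx[:, :, i : i + Do, j : j + Ho, l : l + Wo] += np.tensordot(
                    self.w[:, :, i, j, l], gy, axes=([0], [1])
                )
        if gx is None:
            return None
        return np.ascontiguousarray(np.moveaxis(gx, 0, 1))

    # -- public -------------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.kernel
        B, C, D, H, W = x.shape
        out_shape = (D - k + 1, H - k + 1, W - k + 1)
        self._use_col_now = self._use_col(max(out_shape))
        if self._use_col_now:
            y = self._forward_col(x, out_shape, train)
        else:
            y = self._forward_taps(x, out_shape)
        if self.b is not None:
            y = y + self.b.reshape(1, -1, 1, 1, 1)
        self._x = x if train else None
        return np.ascontiguousarray(y, dtype=F32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = flush_tiny(np.ascontiguousarray(gy, dtype=F32))
        if self.b is not None:
            self.gb[...] = gy.sum(axis=(0, 2, 3, 4))
        if self._use_col_now:
            gx = self._backward_col(gy)
        else:
            gx = self._backward_taps(gy)
        self._x = None
        self._col = None
        return gx

    def param_items(self):
        items = [(self.w, self.gw)]
        if self.b is not None:
            items.append((self.b, self.gb))
        return items

    def state_arrays(self):
        d = {"w": self.w}
        if self.b is not None:
            d["b"] = self.b
        return d


class BatchNorm3d:
    """Per-channel batch normalization with running statistics for inference.

    Inference uses the running mean/variance, so the layer is a fixed affine
    map at prediction time -- this keeps tiled valid-padding inference exactly
    equal to dense inference.
    """

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=F32)
        self.beta = np.zeros(ch, dtype=F32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=F32)
        self.running_var = np.ones(ch, dtype=F32)
        self.momentum = momentum
        self.eps = eps
        #: when True, training uses the (fixed) running statistics, so the
        #: optimized network is exactly the inference-time network
        self.frozen = False
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        use_batch_stats = train and not self.frozen
        if use_batch_stats:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mu
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(1, -1, 1, 1, 1)) * inv.reshape(1, -1, 1, 1, 1)
        y = self.gamma.reshape(1, -1, 1, 1, 1) * xhat + self.beta.reshape(1, -1, 1, 1, 1)
        self._cache = (xhat, inv, use_batch_stats) if train else None
        return y.astype(F32, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = flush_tiny(np.ascontiguousarray(gy, dtype=F32))
        xhat, inv, batch_stats = self._cache
        axes = (0, 2, 3, 4)
        self.ggamma[...] = (gy * xhat).sum(axis=axes)
        self.gbeta[...] = gy.sum(axis=axes)
        g = gy * self.gamma.reshape(1, -1, 1, 1, 1)
        if batch_stats:
            mean_g = g.mean(axis=axes, keepdims=True)
            mean_gx = (g * xhat).mean(axis=axes, keepdims=True)
            gx = inv.reshape(1, -1, 1, 1, 1) * (g - mean_g - xhat * mean_gx)
        else:
            # statistics are constants: the layer is a fixed affine map
            gx = g * inv.reshape(1, -1, 1, 1, 1)
        self._cache = None
        return gx.astype(F32, copy=False)

    def param_items(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def state_arrays(self):
        return {
            "gamma": self.gamma,
            "beta": self.beta,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }


class GroupNorm3d:
    """Group normalization (statistics per sample and channel group).

    Note: the statistics depend on the whole input window, so predictions
    from tiled inference are defined per tile and will not match a dense
    whole-volume pass; batch normalization is the default for that reason.
    """

    def __init__(self, ch: int, groups: int = 4, eps: float = 1e-5):
        if ch % groups != 0:
            raise ValueError(f"channels {ch} not divisible by groups {groups}")
        self.groups = groups
        self.gamma = np.ones(ch, dtype=F32)
        self.beta = np.zeros(ch, dtype=F32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, D, H, W = x.shape
        G = self.groups
        xg = x.reshape(B, G, C // G, D, H, W)
        axes = (2, 3, 4, 5)
        mu = xg.mean(axis=axes, keepdims=True)
        var = xg.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(B, C, D, H, W)
        y = self.gamma.reshape(1, -1, 1, 1, 1) * xhat + self.beta.reshape(1, -1, 1, 1, 1)
        self._cache = (xhat, inv) if train else None
        return y.astype(F32, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = flush_tiny(np.ascontiguousarray(gy, dtype=F32))
        xhat, inv = self._cache
        B, C, D, H, W = gy.shape
        G = self.groups
        self.ggamma[...] = (gy * xhat).sum(axis=(0, 2, 3, 4))
        self.gbeta[...] = gy.sum(axis=(0, 2, 3, 4))
        g = (gy * self.gamma.reshape(1, -1, 1, 1, 1)).reshape(B, G, C // G, D, H, W)
        xh = xhat.reshape(B, G, C // G, D, H, W)
        axes = (2, 3, 4, 5)
        mean_g = g.mean(axis=axes, keepdims=True)
        mean_gx = (g * xh).mean(axis=axes, keepdims=True)
        gx = inv * (g - mean_g - xh * mean_gx)
        self._cache = None
        return gx.reshape(B, C, D, H, W).astype(F32, copy=False)

    def param_items(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def state_arrays(self):
        return {"gamma": self.gamma, "beta": self.beta}


class Identity:
    def forward(self, x, train=False):
        return x

    def backward(self, gy):
        return gy

    def param_items(self):
        return []

    def state_arrays(self):
        return {}


class ELU:
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pos = x > 0
        y = np.where(pos, x, self.alpha * np.expm1(np.minimum(x, 0.0)))
        y = y.astype(F32, copy=False)
        self._cache = (pos, y) if train else None
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        pos, y = self._cache
        self._cache = None
        return np.where(pos, gy, gy * (y + self.alpha)).astype(F32, copy=False)

    def param_items(self):
        return []

    def state_arrays(self):
        return {}


class ConvBlock:
    """Conv3d -> normalization -> ELU."""

    def __init__(self, in_ch, out_ch, kernel, norm, rng, groups=4,
                 compute_input_grad=True):
        self.conv = Conv3d(in_ch, out_ch, kernel, rng, bias=(norm == "none"),
                           compute_input_grad=compute_input_grad)
        if norm == "batch":
            self.norm = BatchNorm3d(out_ch)
        elif norm == "group":
            self.norm = GroupNorm3d(out_ch, groups=groups)
        elif norm == "none":
            self.norm = Identity()
        else:
            raise ValueError(f"unknown norm: {norm}")
        self.act = ELU()

    def forward(self, x, train=False):
        return self.act.forward(self.norm.forward(self.conv.forward(x, train), train), train)

    def backward(self, gy):
        return self.conv.backward(self.norm.backward(self.act.backward(gy)))

    def param_items(self):
        return self.conv.param_items() + self.norm.param_items()

    def state_arrays(self):
        d = {f"conv.{k}": v for k, v in self.conv.state_arrays().items()}
        d.update({f"norm.{k}": v for k, v in self.norm.state_arrays().items()})
        return d


class MaxPool3d:
    """2x2x2 max pooling (input sides must be even)."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, D, H, W = x.shape
        if D % 2 or H % 2 or W % 2:
            raise ValueError(f"pool input sides must be even, got {(D, H, W)}")
        xr = (
            x.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(B, C, D // 2, H // 2, W // 2, 8)
        )
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (B, C, D, H, W)) if train else None
        return np.ascontiguousarray(y)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = flush_tiny(np.ascontiguousarray(gy, dtype=F32))
        idx, (B, C, D, H, W) = self._cache
        self._cache = None
        g = np.zeros((B, C, D // 2, H // 2, W // 2, 8), dtype=F32)
        np.put_along_axis(g, idx[..., None], gy[..., None].astype(F32), axis=-1)
        gx = (
            g.reshape(B, C, D // 2, H // 2, W // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(B, C, D, H, W)
        )
        return np.ascontiguousarray(gx)

    def param_items(self):
        return []

    def state_arrays(self):
        return {}


def _upsample_matrix(n: int) -> np.ndarray:
    """Factor-2 half-voxel linear interpolation followed by a 1-voxel
    validity crop on each side: n samples -> 2n - 2 samples, every output an
    exact interior interpolation (no clamped border samples)."""
    if n < 2:
        raise ValueError("upsample input side must be >= 2")
    m = np.zeros((2 * n - 2, n), dtype=F32)
    for i in range(2 * n - 2):
        j = i + 1  # index on the uncropped 2n grid
        if j % 2 == 0:
            k = j // 2
            m[i, k] = 0.75
            m[i, k - 1] = 0.25
        else:
            k = (j - 1) // 2
            m[i, k] = 0.75
            m[i, k + 1] = 0.25
    return m


_UP_CACHE: dict[int, np.ndarray] = {}


def _up_matrix(n: int) -> np.ndarray:
    if n not in _UP_CACHE:
        _UP_CACHE[n] = _upsample_matrix(n)
    return _UP_CACHE[n]


def _apply_axis(x: np.ndarray, m: np.ndarray, axis: int) -> np.ndarray:
    moved = np.moveaxis(x, axis, -1)
    out = moved @ m.T
    return np.moveaxis(out, -1, axis)


class LinearUpsample3d:
    """Trilinear factor-2 upsampling, cropped to its exact interior (2n-2)."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape if train else None
        for axis in (2, 3, 4):
            x = _apply_axis(x, _up_matrix(x.shape[axis]), axis)
        return np.ascontiguousarray(x, dtype=F32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = flush_tiny(np.ascontiguousarray(gy, dtype=F32))
        in_shape = self._shape
        self._shape = None
        g = gy
        for axis in (4, 3, 2):
            m = _up_matrix(in_shape[axis])
            moved = np.moveaxis(g, axis, -1)
            moved = moved @ m
            g = np.moveaxis(moved, -1, axis)
        return np.ascontiguousarray(g, dtype=F32)

    @staticmethod
    def output_size(n: int) -> int:
        return 2 * n - 2

    def param_items(self):
        return []

    def state_arrays(self):
        return {}


class CropConcat:
    """Center-crop the skip feature map to the decoder size and concatenate
    it (skip channels first) along the channel axis."""

    def __init__(self):
        self._cache = None

    def forward(self, skip: np.ndarray, up: np.ndarray, train: bool = False) -> np.ndarray:
        slices = [slice(None), slice(None)]
        for a in (2, 3, 4):
            diff = skip.shape[a] - up.shape[a]
            if diff < 0 or diff % 2:
                raise ValueError(
                    f"cannot center-crop skip {skip.shape} to {up.shape} on axis {a}"
                )
            slices.append(slice(diff // 2, diff // 2 + up.shape[a]))
        cropped = skip[tuple(slices)]
        y = np.concatenate([cropped, up], axis=1)
        self._cache = (skip.shape, tuple(slices), skip.shape[1]) if train else None
        return np.ascontiguousarray(y)

    def backward(self, gy: np.ndarray):
        skip_shape, slices, c_skip = self._cache
        self._cache = None
        g_skip = np.zeros(skip_shape, dtype=F32)
        g_skip[slices] = gy[:, :c_skip]
        g_up = np.ascontiguousarray(gy[:, c_skip:])
        return g_skip, g_up

    def param_items(self):
        return []

    def state_arrays(self):
        return {}
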