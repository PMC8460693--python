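"""The valid-padding 3-D U-net: configuration, shape trace and assembly.

Architecture: an encoder of ``levels`` stages (3x3x3 valid convolutions with
normalization and ELU, then 2x2x2 max pooling), a bottleneck stage, and a
decoder that doubles resolution with exact linear upsampling, concatenates
the centrally cropped skip feature map, and applies further convolutions.  A
final 1x1x1 convolution with a single sigmoid output neuron produces the
per-voxel probability.

Because every convolution is valid-padded, an input of side N yields an
output of side N - 2*margin.  The margin is a build-time contract: the
symbolic shape trace must reproduce exactly the configured margin or the
build fails naming the achieved shrinkage.  The reference configuration
(3 levels, filters 16/32/64, encoder convs (2,2,1), bottleneck 1, decoder
convs (1,0,1)) has margin 30, so a 92-cube input maps to a 32-cube output.

Upsampling is factor-2 linear interpolation cropped to its exact interior
(n -> 2n - 2): every retained sample is a true interpolation of real feature
values, which is what makes tiled inference bit-compatible with a dense pass.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .layers import F32, ConvBlock, Conv3d, CropConcat, LinearUpsample3d, MaxPool3d

__all__ = [
    "UNetConfig",
    "UNetConfigError",
    "ShapeTraceError",
    "UNet3D",
    "trace_output_size",
    "find_admissible_size",
]


class UNetConfigError(ValueError):
    pass


class ShapeTraceError(ValueError):
    """The input size is not admissible for the configured network."""


@dataclass(frozen=True)
class UNetConfig:
    """Static architecture description.

    ``encoder_convs`` / ``decoder_convs`` are per level, full resolution
    first; ``filters_per_level`` likewise.  ``margin`` is the required
    per-side spatial shrinkage of the assembled network.
    """

    kernel: int = 3
    levels: int = 3
    filters_per_level: tuple[int, ...] = (16, 32, 64)
    bottleneck_filters: int = 64
    encoder_convs: tuple[int, ...] = (2, 2, 1)
    bottleneck_convs: int = 1
    decoder_convs: tuple[int, ...] = (1, 0, 1)
    activation: str = "elu"
    norm: str = "batch"  # "batch" | "group" | "none"
    groups: int = 4
    padding: str = "valid"
    margin: int = 30
    #: initial bias of the output neuron; the logit of the expected lesion
    #: prevalence is a good choice (stabilises early Dice optimization)
    output_bias: float = 0.0

    def __post_init__(self):
        if self.padding != "valid":
            raise UNetConfigError("only valid padding is supported")
        if self.activation != "elu":
            raise UNetConfigError("only ELU activations are supported")
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise UNetConfigError("kernel must be odd and positive")
        if len(self.filters_per_level) != self.levels:
            raise UNetConfigError("filters_per_level must have one entry per level")
        if len(self.encoder_convs) != self.levels or len(self.decoder_convs) != self.levels:
            raise UNetConfigError("encoder/decoder convs must have one entry per level")

    @property
    def total_stride(self) -> int:
        return 2**self.levels

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "UNetConfig":
        d = json.loads(s)
        for key in ("filters_per_level", "encoder_convs", "decoder_convs"):
            d[key] = tuple(d[key])
        return cls(**d)


def trace_output_size(cfg: UNetConfig, n: int) -> int:
    """Symbolic per-axis shape trace; raises ShapeTraceError when ``n`` is
    not admissible (odd size at a pooling step, or a feature map vanishing)."""
    loss = cfg.kernel - 1
    s = n
    for lvl in range(cfg.levels):
        s -= loss * cfg.encoder_convs[lvl]
        if s < 2:
            raise ShapeTraceError(f"encoder level {lvl} reduces side to {s}")
        if s % 2:
            raise ShapeTraceError(f"pooling at level {lvl} sees odd side {s}")
        s //= 2
    s -= loss * cfg.bottleneck_convs
    if s < 2:
        raise ShapeTraceError(f"bottleneck reduces side to {s}")
    for lvl in reversed(range(cfg.levels)):
        s = 2 * s - 2  # exact-interior linear upsampling
        s -= loss * cfg.decoder_convs[lvl]
        if s < 1:
            raise ShapeTraceError(f"decoder level {lvl} reduces side to {s}")
    return s


def find_admissible_size(cfg: UNetConfig, start: int = 1, limit: int = 4096) -> int:
    """Smallest input side >= ``start`` the network accepts."""
    for n in range(max(start, 1), limit):
        try:
            trace_output_size(cfg, n)
            return n
        except ShapeTraceError:
            continue
    raise UNetConfigError("no admissible input size found")  # pragma: no cover


def _validate_margin(cfg: UNetConfig) -> None:
    n = find_admissible_size(cfg)
    out = trace_output_size(cfg, n)
    shrink = n - out
    if shrink != 2 * cfg.margin:
        raise UNetConfigError(
            f"configuration shrinks the input by {shrink / 2:g} voxels per side, "
            f"but margin={cfg.margin} was required"
        )


class UNet3D:
    """Assembled network; ``forward`` maps (B, 1, N, N, N) logits to
    (B, 1, N-2*margin, ...).  Deterministic initialization under a fixed seed."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        _validate_margin(cfg)
        self.cfg = cfg
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        k, norm, groups = cfg.kernel, cfg.norm, cfg.groups

        self.enc_blocks: list[list[ConvBlock]] = []
        self.pools: list[MaxPool3d] = []
        skip_ch: list[int] = []
        ch = 1
        first = True
        for lvl in range(cfg.levels):
            stage = []
            for _ in range(cfg.encoder_convs[lvl]):
                stage.append(
                    ConvBlock(
                        ch, cfg.filters_per_level[lvl], k, norm, rng, groups,
                        # the network input needs no gradient
                        compute_input_grad=not first,
                    )
                )
                first = False
                ch = cfg.filters_per_level[lvl]
            if cfg.encoder_convs[lvl] == 0:  # pragma: no cover - degenerate config
                raise UNetConfigError("encoder stages need at least one convolution")
            self.enc_blocks.append(stage)
            skip_ch.append(ch)
            self.pools.append(MaxPool3d())

        self.bottleneck: list[ConvBlock] = []
        for _ in range(cfg.bottleneck_convs):
            self.bottleneck.append(ConvBlock(ch, cfg.bottleneck_filters, k, norm, rng, groups))
            ch = cfg.bottleneck_filters

        self.ups: list[LinearUpsample3d] = []
        self.concats: list[CropConcat] = []
        self.dec_blocks: list[list[ConvBlock]] = []
        for lvl in reversed(range(cfg.levels)):
            self.ups.append(LinearUpsample3d())
            self.concats.append(CropConcat())
            ch = ch + skip_ch[lvl]
            stage = []
            for _ in range(cfg.decoder_convs[lvl]):
                stage.append(ConvBlock(ch, cfg.filters_per_level[lvl], k, norm, rng, groups))
                ch = cfg.filters_per_level[lvl]
            self.dec_blocks.append(stage)
        self.out_conv = Conv3d(ch, 1, 1, rng, bias=True)
        self.out_conv.b[...] = cfg.output_bias

    # -- plumbing ---------------------------------------------------------

    @property
    def margin(self) -> int:
        return self.cfg.margin

    @property
    def total_stride(self) -> int:
        return self.cfg.total_stride

    def set_norm_frozen(self, frozen: bool) -> None:
        """Freeze/unfreeze batch-norm statistics (no-op for other norms)."""
        for layer in self._all_layers():
            norm = getattr(layer, "norm", None)
            if norm is not None and hasattr(norm, "frozen"):
                norm.frozen = frozen

    def is_admissible(self, n: int) -> bool:
        try:
            trace_output_size(self.cfg, n)
            return True
        except ShapeTraceError:
            return False

    def _all_layers(self):
        for stage in self.enc_blocks:
            yield from stage
        yield from self.pools
        yield from self.bottleneck
        yield from self.ups
        yield from self.concats
        for stage in self.dec_blocks:
            yield from stage
        yield self.out_conv

    def param_items(self):
        items = []
        for layer in self._all_layers():
            items.extend(layer.param_items())
        return items

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self._all_layers()):
            for name, arr in layer.state_arrays().items():
                state[f"layer{i:03d}.{name}"] = arr
        return state

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_dict().items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        if set(own) != set(state):
            raise ValueError("state does not match this architecture")
        for key, arr in own.items():
            arr[...] = state[key]

    # -- compute ----------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of input windows (B, 1, N, N, N)."""
        x = np.ascontiguousarray(x, dtype=F32)
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError(f"expected (B, 1, D, H, W) input, got {x.shape}")
        for a, n in enumerate(x.shape[2:]):
            try:
                trace_output_size(self.cfg, n)
            except ShapeTraceError as e:
                raise ShapeTraceError(f"input side {n} on axis {a}: {e}") from None
        h = x
        skips = []
        for lvl in range(self.cfg.levels):
            for block in self.enc_blocks[lvl]:
                h = block.forward(h, train)
            skips.append(h)
            h = self.pools[lvl].forward(h, train)
        for block in self.bottleneck:
            h = block.forward(h, train)
        for i, lvl in enumerate(reversed(range(self.cfg.levels))):
            h = self.ups[i].forward(h, train)
            h = self.concats[i].forward(skips[lvl], h, train)
            for block in self.dec_blocks[i]:
                h = block.forward(h, train)
        return self.out_conv.forward(h, train)

    def backward(self, glogits: np.ndarray) -> None:
        """Backpropagate loss gradients w.r.t. the logits; parameter
        gradients land in each layer's buffers."""
        g = self.out_conv.backward(np.ascontiguousarray(glogits, dtype=F32))
        skip_grads: dict[int, np.ndarray] = {}
        for i in reversed(range(self.cfg.levels)):
            lvl = self.cfg.levels - 1 - i  # resolution level of decoder stage i
            for block in reversed(self.dec_blocks[i]):
                g = block.backward(g)
            g_skip, g = self.concats[i].backward(g)
            skip_grads[lvl] = g_skip
            g = self.ups[i].backward(g)
        for block in reversed(self.bottleneck):
            g = block.backward(g)
        for lvl in reversed(range(self.cfg.levels)):
            g = self.pools[lvl].backward(g)
            g = g + skip_grads[lvl]
            for block in reversed(self.enc_blocks[lvl]):
                g = block.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities in eval mode (running-stat normalization).

        Computed in float64 so that strongly saturated outputs retain
        distinct ranks for ROC analysis.
        """
        logits = self.forward(x, train=False)
        return sigmoid(logits.astype(np.float64))

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        state = self.state_dict()
        np.savez_compressed(
            path,
            __config__=np.frombuffer(self.cfg.to_json().encode(), dtype=np.uint8),
            __seed__=np.array([self.seed]),
            **state,
        )

    @classmethod
    def load(cls, path) -> "UNet3D":
        with np.load(path) as data:
            cfg = UNetConfig.from_json(bytes(data["__config__"].tobytes()).decode())
            seed = int(data["__seed__"][0])
            net = cls(cfg, seed=seed)
            state = {k: data[k] for k in data.files if not k.startswith("__")}
        net.load_state(state)
        return net


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=F32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
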