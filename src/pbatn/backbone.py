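"""PBATn feature extractor.

A ResNet-50-shaped five-stage network (stem + stages of 3, 4, 6, 3
bottleneck blocks) in which every bottleneck main path runs

    temporal shift → 1×1 conv → local self-attention → 1×1 conv → channel attention

with group normalization (32 groups by default) and ReLU after each 7×7 and
1×1 convolution.  The temporal shift exchanges a 1/8 fraction of channels
with the previous and next frame at zero parameter cost; the self-attention
layer replaces the classical 3×3 convolution with a scaled-dot-product
attention over each position's 3×3 neighborhood (learned relative-position
key terms, multi-head); the channel attention is a squeeze-excite gate.

Feeding an 8×3×224×224 clip through the default configuration traverses the
stage output chain 64×112×112 → 64×56×56 → 256×56×56 → 512×28×28 →
1024×14×14 → 2048×7×7 → 2048×1×1 and yields one 2048-dim feature per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .autograd import (
    Tensor,
    as_tensor,
    concatenate,
    einsum2,
    max_pool2d,
    no_grad,
    softmax,
    unfold,
)

__all__ = [
    "BackboneConfig",
    "temporal_shift",
    "avg_pool2d",
    "LocalSelfAttention",
    "ChannelAttention",
    "GNReLU",
    "Bottleneck",
    "Backbone",
    "backbone_forward",
]


@dataclass
class BackboneConfig:
    """Architecture hyperparameters.

    ``stage_widths`` are bottleneck widths; block output channels are four
    times the width.  Every normalized channel count must be divisible by
    ``gn_groups``; bottleneck widths must be divisible by
    ``attention_heads``; block outputs by ``ca_reduction``.
    """

    stage_depths: tuple = (3, 4, 6, 3)
    stage_widths: tuple = (64, 128, 256, 512)
    stem_channels: int = 64
    gn_groups: int = 32
    input_frames: int = 8
    shift_fraction: float = 0.125
    attention_window: int = 3
    attention_heads: int = 4
    ca_reduction: int = 16

    def __post_init__(self):
        self.stage_depths = tuple(int(d) for d in self.stage_depths)
        self.stage_widths = tuple(int(w) for w in self.stage_widths)
        if len(self.stage_depths) != len(self.stage_widths):
            raise ValueError("stage_depths and stage_widths must align")
        for c in (self.stem_channels, *self.stage_widths, *self.out_widths):
            if c % self.gn_groups != 0:
                raise ValueError(
                    f"channel count {c} not divisible by gn_groups={self.gn_groups}"
                )
        for w in self.stage_widths:
            if w % self.attention_heads != 0:
                raise ValueError(
                    f"width {w} not divisible by attention_heads={self.attention_heads}"
                )
        for c in self.out_widths:
            if c % self.ca_reduction != 0:
                raise ValueError(
                    f"output width {c} not divisible by ca_reduction={self.ca_reduction}"
                )
        if self.attention_window % 2 == 0:
            raise ValueError(f"attention window must be odd, got {self.attention_window}")

    @property
    def out_widths(self) -> tuple:
        return tuple(4 * w for w in self.stage_widths)

    @property
    def feature_dim(self) -> int:
        return self.out_widths[-1]

    @classmethod
    def tiny(cls) -> "BackboneConfig":
        """Reduced preset for CPU-scale experiments on small synthetic clips."""
        return cls(
            stage_depths=(1, 1, 1, 1),
            stage_widths=(8, 16, 32, 64),
            stem_channels=16,
            gn_groups=4,
            attention_heads=2,
            ca_reduction=4,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_depths"] = list(self.stage_depths)
        d["stage_widths"] = list(self.stage_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        return cls(**d)


# -- temporal shift ----------------------------------------------------------


def temporal_shift(x, fraction: float = 0.125, frames: int | None = None):
    """Shift a channel fraction across the frame axis.

    ``x`` is T×C×H×W (one clip) or B×T×C×H×W.  The first ⌊C·fraction⌋
    channels are shifted forward in time (frame t receives frame t−1), the
    next ⌊C·fraction⌋ backward (frame t receives frame t+1); remaining
    channels pass through.  Vacated boundary slots are zero-filled.  Returns
    the same type (ndarray in, ndarray out).
    """
    was_array = not isinstance(x, Tensor)
    t = as_tensor(x)
    squeeze = t.ndim == 4
    if squeeze:
        t = t.reshape((1,) + t.shape)
    if t.ndim != 5:
        raise ValueError(f"expected T×C×H×W or B×T×C×H×W, got shape {t.shape}")
    b, T, c, h, w = t.shape
    if T < 1:
        raise ValueError("temporal_shift needs at least one frame")
    if fraction == 0:
        out = t
    else:
        nshift = int(c * fraction)
        if nshift < 1:
            raise ValueError(
                f"shift fraction {fraction} moves no channels at C={c}"
            )
        if 2 * nshift > c:
            raise ValueError("shift fraction too large: both directions exceed C")
        zeros = Tensor(np.zeros((b, 1, nshift, h, w), dtype=np.float32))
        if T == 1:
            fwd = zeros
            bwd = zeros
        else:
            fwd = concatenate([zeros, t[:, :-1, :nshift]], axis=1)
            bwd = concatenate([t[:, 1:, nshift : 2 * nshift], zeros], axis=1)
        parts = [fwd, bwd]
        if 2 * nshift < c:
            parts.append(t[:, :, 2 * nshift :])
        out = concatenate(parts, axis=2)
    if squeeze:
        out = out.reshape(out.shape[1:])
    return out.data if was_array else out


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k×k average pooling (spatial dims must divide by k)."""
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims {h}×{w} not divisible by pool size {k}")
    return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))


# -- attention layers --------------------------------------------------------


class LocalSelfAttention(nn.Module):
    """Multi-head scaled-dot-product attention over a local window.

    Queries, keys and values come from learned 1×1 projections (the three
    shared key-derivation matrices).  For each output position the attention
    distribution runs over its ``window``×``window`` neighborhood
    (zero-padded at borders) with a learned relative-position term added to
    the scaled dot product.  A stride of 2 is realized by 2×2 average
    pooling after attention.
    """

    def __init__(
        self,
        channels: int,
        heads: int = 4,
        window: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if window % 2 == 0:
            raise ValueError(f"attention window must be odd, got {window}")
        if channels % heads != 0:
            raise ValueError(f"channels {channels} not divisible by heads {heads}")
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.heads = heads
        self.window = window
        self.stride = stride
        self.head_dim = channels // heads
        self.query = nn.Conv2d(channels, channels, 1, rng=rng)
        self.key = nn.Conv2d(channels, channels, 1, rng=rng)
        self.value = nn.Conv2d(channels, channels, 1, rng=rng)
        self.rel_pos = nn.Parameter(
            np.zeros((heads, window * window), dtype=np.float32)
        )

    def attention_weights(self, x) -> np.ndarray:
        """Softmax-normalized weights, shape N×heads×window²×(H·W)."""
        with no_grad():
            _, attn = self._attend(as_tensor(x))
        return attn.data

    def _attend(self, x: Tensor) -> tuple[Tensor, Tensor]:
        n, c, h, w = x.shape
        hd, nh, ww = self.head_dim, self.heads, self.window * self.window
        pad = self.window // 2
        q = self.query(x).reshape(n, nh, hd, h * w)
        kc = unfold(self.key(x), self.window, 1, pad).reshape(n, nh, hd, ww, h * w)
        vc = unfold(self.value(x), self.window, 1, pad).reshape(n, nh, hd, ww, h * w)
        logits = einsum2("nhdl,nhdwl->nhwl", q, kc) * (1.0 / np.sqrt(hd))
        logits = logits + self.rel_pos.reshape(1, nh, ww, 1)
        attn = softmax(logits, axis=2)
        out = einsum2("nhwl,nhdwl->nhdl", attn, vc).reshape(n, c, h, w)
        return out, attn

    def forward(self, x: Tensor) -> Tensor:
        out, _ = self._attend(x)
        if self.stride == 2:
            out = avg_pool2d(out, 2)
        return out


class ChannelAttention(nn.Module):
    """Squeeze-excite gate: global average pool → C/r → ReLU → C → sigmoid."""

    def __init__(
        self, channels: int, reduction: int = 16, rng: np.random.Generator | None = None
    ):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(
                f"channels {channels} not divisible by reduction {reduction}"
            )
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.squeeze = nn.Linear(channels, channels // reduction, rng=rng)
        self.excite = nn.Linear(channels // reduction, channels, rng=rng)

    def scale(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3))  # N×C global receptive field
        return self.excite(self.squeeze(pooled).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        return x * self.scale(x).reshape(n, c, 1, 1)


class GNReLU(nn.Module):
    def __init__(self, groups: int, channels: int):
        super().__init__()
        self.norm = nn.GroupNorm(groups, channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(x).relu()


def channel_attention(x: np.ndarray, module: ChannelAttention) -> np.ndarray:
    """Functional wrapper: apply a channel-attention gate to C×H×W or N×C×H×W."""
    arr = np.asarray(x, dtype=np.float32)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    with no_grad():
        out = module(Tensor(arr)).data
    return out[0] if squeeze else out


# -- residual blocks ---------------------------------------------------------


class Bottleneck(nn.Module):
    """Residual bottleneck with the temporally-shifted attention main path.

    ``kind='convolution'`` carries a projection (1×1 conv + GN) skip path and
    may stride; ``kind='identity'`` keeps a plain identity skip.  The main
    path output is multiplied by a zero-initialized scalar so every block is
    an identity at initialization.
    """

    def __init__(
        self,
        kind: str,
        in_channels: int,
        width: int,
        stride: int,
        cfg: BackboneConfig,
        rng: np.random.Generator,
    ):
        super().__init__()
        if kind not in ("convolution", "identity"):
            raise ValueError(f"unknown block kind {kind!r}")
        out_channels = 4 * width
        if kind == "identity" and (in_channels != out_channels or stride != 1):
            raise ValueError("identity block cannot change channels or stride")
        self.kind = kind
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.stride = stride
        self.frames = cfg.input_frames
        self.shift_fraction = cfg.shift_fraction
        g = cfg.gn_groups
        self.conv_reduce = nn.Conv2d(in_channels, width, 1, rng=rng)
        self.gn_reduce = GNReLU(g, width)
        self.attn = LocalSelfAttention(
            width,
            heads=cfg.attention_heads,
            window=cfg.attention_window,
            stride=stride,
            rng=rng,
        )
        self.gn_attn = GNReLU(g, width)
        self.conv_expand = nn.Conv2d(width, out_channels, 1, rng=rng)
        self.gn_expand = nn.GroupNorm(g, out_channels)
        self.ca = ChannelAttention(out_channels, cfg.ca_reduction, rng=rng)
        self.res_scale = nn.Parameter(np.zeros((), dtype=np.float32))
        if kind == "convolution":
            self.proj = nn.Conv2d(in_channels, out_channels, 1, stride=stride, rng=rng)
            self.gn_proj = nn.GroupNorm(g, out_channels)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        if n % self.frames != 0:
            raise ValueError(
                f"batch of {n} frames is not a whole number of {self.frames}-frame clips"
            )
        y = x.reshape(n // self.frames, self.frames, c, h, w)
        y = temporal_shift(y, self.shift_fraction).reshape(n, c, h, w)
        y = self.gn_reduce(self.conv_reduce(y))
        y = self.gn_attn(self.attn(y))
        y = self.gn_expand(self.conv_expand(y))
        y = self.ca(y) * self.res_scale
        skip = x if self.proj is None else self.gn_proj(self.proj(x))
        return (y + skip).relu()


class Backbone(nn.Module):
    """Stem + four bottleneck stages + adaptive average pooling."""

    STAGE_NAMES = ("conv2_x", "conv3_x", "conv4_x", "conv5_x")

    def __init__(self, cfg: BackboneConfig | None = None, seed: int | None = None):
        super().__init__()
        self.cfg = cfg or BackboneConfig()
        rng = np.random.default_rng(seed)
        c = self.cfg
        self.stem = nn.Conv2d(3, c.stem_channels, 7, stride=2, padding=3, rng=rng)
        self.stem_gn = GNReLU(c.gn_groups, c.stem_channels)
        self.stages: list[nn.Sequential] = []
        in_ch = c.stem_channels
        for si, (depth, width) in enumerate(zip(c.stage_depths, c.stage_widths)):
            stride = 1 if si == 0 else 2  # conv2_1 keeps stride 1, later stages halve
            blocks = [Bottleneck("convolution", in_ch, width, stride, c, rng)]
            in_ch = 4 * width
            for _ in range(depth - 1):
                blocks.append(Bottleneck("identity", in_ch, width, 1, c, rng))
            self.stages.append(nn.Sequential(*blocks))

    @property
    def feature_dim(self) -> int:
        return self.cfg.feature_dim

    def forward_maps(self, x: Tensor) -> tuple[Tensor, dict]:
        """Run up to the last stage; return final maps and stage shape chain."""
        n, c, h, w = x.shape
        if c != 3:
            raise ValueError(f"expected 3 input channels, got {c}")
        if h % 32 or w % 32:
            raise ValueError(f"spatial dims {h}×{w} must be divisible by 32")
        shapes = {}
        y = self.stem_gn(self.stem(x))
        shapes["conv1"] = y.shape[1:]
        y = max_pool2d(y, 3, 2, 1)
        shapes["maxpool"] = y.shape[1:]
        for name, stage in zip(self.STAGE_NAMES, self.stages):
            y = stage(y)
            shapes[name] = y.shape[1:]
        return y, shapes

    def forward(self, x: Tensor) -> Tensor:
        """N×3×H×W frames → N×C pooled per-frame features."""
        maps, _ = self.forward_maps(x)
        pooled = maps.mean(axis=(2, 3))
        return pooled


def backbone_forward(
    backbone: Backbone, batch: np.ndarray, return_shapes: bool = False
):
    """Evaluate a T×3×H×W (or B·T×3×H×W) frame batch to per-frame features.

    Returns a T×C float array; with ``return_shapes`` also the ordered stage
    output-shape chain (conv1 … conv5_x plus the pooled feature).
    """
    arr = np.asarray(batch, dtype=np.float32)
    if arr.ndim != 4:
        raise ValueError(f"expected a T×3×H×W batch, got shape {arr.shape}")
    backbone.eval()
    with no_grad():
        maps, shapes = backbone.forward_maps(Tensor(arr))
        feats = maps.mean(axis=(2, 3)).data
    backbone.train()
    if return_shapes:
        shapes["avgpool"] = (feats.shape[1], 1, 1)
        return feats, shapes
    return feats
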