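"""The improved DeepLabv3+ segmentation network.

The encoder head replaces the parallel atrous spatial pyramid (ASPP) with a
densely connected cascade (DenseASPP): atrous layers of strictly increasing
dilation, each consuming the channel-concatenation of the input and every
earlier layer's output. Where the parallel pyramid's receptive field is the
maximum over its branches, the dense cascade's receptive fields add::

    R_{K,d}        = (K - 1) * d + 1                      (one atrous layer)
    R_ASPP         = max_d R_{K,d}
    R_DenseASPP    = sum_d R_{K,d} - (n_layers - 1)

A strip-pooling (SP) block is inserted on the high-level feature path: row
and column means are expanded by 1-D convolutions, summed positionwise, and
squashed into a sigmoid gate multiplied onto the features — an attention
pattern suited to long thin structures (bar-shaped blades, slender petioles).

The backbone is pluggable; the built-in "tiny" backbone is a 4-stage
convolutional encoder (output stride 16, taps at stride 4 and 16) sized for
CPU-scale experiments. A decoder upsamples the head output, concatenates
projected low-level features and refines with 3x3 convolutions, emitting a
full-resolution per-class score map.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from . import nn

__all__ = [
    "atrous_rf",
    "aspp_rf",
    "denseaspp_rf",
    "strip_pool_rows",
    "strip_pool_cols",
    "StripPooling",
    "DenseASPPConfig",
    "DenseASPP",
    "ASPP",
    "SegModelConfig",
    "SegModel",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# receptive-field algebra


def atrous_rf(kernel: int, dilation: int) -> int:
    """Receptive field of one atrous convolution: (K - 1) * d + 1."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be odd and >= 1")
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    return (kernel - 1) * dilation + 1


def aspp_rf(rates: list[int], kernel: int = 3) -> int:
    """Receptive field of the parallel pyramid: the largest branch wins."""
    if not rates:
        raise ValueError("rates must be nonempty")
    return max(atrous_rf(kernel, d) for d in rates)


def denseaspp_rf(rates: list[int], kernel: int = 3) -> int:
    """Receptive field of the dense cascade: branch fields add, minus the
    (n - 1) shared centers."""
    if not rates:
        raise ValueError("rates must be nonempty")
    return sum(atrous_rf(kernel, d) for d in rates) - (len(rates) - 1)


# ---------------------------------------------------------------------------
# strip pooling


def strip_pool_rows(x: np.ndarray) -> np.ndarray:
    """Row means of a (C, H, W) feature map -> (C, H)."""
    x = np.asarray(x)
    return x.mean(axis=-1)


def strip_pool_cols(x: np.ndarray) -> np.ndarray:
    """Column means of a (C, H, W) feature map -> (C, W)."""
    x = np.asarray(x)
    return x.mean(axis=-2)


class StripPooling(nn.Module):
    """Strip-pooling gate.

    Row/column mean pools are expanded along the pooled axis by kernel-3 1-D
    convolutions, broadcast back to H x W, summed positionwise, passed through
    a 1x1 convolution and a sigmoid, and multiplied elementwise onto the
    input. Output shape equals input shape; zero inputs stay zero.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv_h = nn.Conv2d(channels, channels, (3, 1), rng=rng)
        self.conv_v = nn.Conv2d(channels, channels, (1, 3), rng=rng)
        self.fuse = nn.Conv2d(channels, channels, 1, rng=rng)

    def set_identity(self) -> None:
        """Make both expansion convolutions and the fusion convolution pass
        their input through unchanged (used to verify the closed-form trace)."""
        for conv, (kh, kw) in ((self.conv_h, (3, 1)), (self.conv_v, (1, 3)),
                               (self.fuse, (1, 1))):
            w = np.zeros_like(conv.weight.data)
            c = w.shape[0]
            w[np.arange(c), np.arange(c), kh // 2, kw // 2] = 1.0
            conv.weight.data = w
            conv.bias.data[...] = 0.0

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        n, c, h, w = x.shape
        yh = self.conv_h(nn.mean_axis(x, 3))          # (N, C, H, 1)
        yv = self.conv_v(nn.mean_axis(x, 2))          # (N, C, 1, W)
        y = nn.add(nn.broadcast_to(yh, (n, c, h, w)),
                   nn.broadcast_to(yv, (n, c, h, w)))
        gate = nn.sigmoid(self.fuse(y))
        return nn.mul(x, gate)


# ---------------------------------------------------------------------------
# pyramid heads


@dataclasses.dataclass(frozen=True)
class DenseASPPConfig:
    """Dilation schedule of the dense cascade; rates strictly increase so the
    smallest rate sits at the bottom and the largest at the top."""

    dilation_rates: tuple[int, ...] = (3, 6, 12, 18)
    mid_channels: int = 64
    kernel: int = 3

    def __post_init__(self):
        if len(self.dilation_rates) < 1:
            raise ValueError("need at least one dilation rate")
        if any(b <= a for a, b in zip(self.dilation_rates, self.dilation_rates[1:])):
            raise ValueError("dilation rates must be strictly increasing")
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError("kernel must be odd")
        if self.mid_channels < 1:
            raise ValueError("mid_channels must be >= 1")


def _conv_bn_relu(cin, cout, k, rng, dilation=1, stride=1) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(cin, cout, k, stride=stride, dilation=dilation, rng=rng),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


class DenseASPP(nn.Module):
    """Densely connected atrous cascade.

    Layer l sees ``concat(x, y_1, ..., y_{l-1})``, reduces channels with a 1x1
    convolution, then applies a 3x3 atrous convolution at its dilation rate;
    the module output is ``concat(x, y_1, ..., y_n)`` with
    C + n * mid_channels channels and unchanged spatial size.
    """

    def __init__(self, in_channels: int, cfg: DenseASPPConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.blocks: list[nn.Sequential] = []
        c = in_channels
        for i, d in enumerate(cfg.dilation_rates):
            block = nn.Sequential(
                nn.Conv2d(c, cfg.mid_channels, 1, rng=rng),
                nn.BatchNorm2d(cfg.mid_channels),
                nn.ReLU(),
                nn.Conv2d(cfg.mid_channels, cfg.mid_channels, cfg.kernel,
                          dilation=d, rng=rng),
                nn.BatchNorm2d(cfg.mid_channels),
                nn.ReLU(),
            )
            self._modules[f"block{i}"] = block
            self.blocks.append(block)
            c += cfg.mid_channels
        self.out_channels = c

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        feats = [x]
        for block in self.blocks:
            inp = feats[0] if len(feats) == 1 else nn.concat(feats, axis=1)
            feats.append(block(inp))
        return nn.concat(feats, axis=1)


class ASPP(nn.Module):
    """Plain parallel pyramid baseline: a 1x1 branch plus one 3x3 atrous
    branch per rate and a global-pooling branch, fused by concatenation."""

    def __init__(self, in_channels: int, rates: tuple[int, ...],
                 mid_channels: int = 64, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.branches: list[nn.Module] = [_conv_bn_relu(in_channels, mid_channels, 1, rng)]
        for d in rates:
            self.branches.append(
                _conv_bn_relu(in_channels, mid_channels, 3, rng, dilation=d))
        # no batchnorm on the 1x1 pooled branch: batch statistics over a
        # single spatial position are degenerate and would zero its gradients
        self.pool_proj = nn.Sequential(
            nn.Conv2d(in_channels, mid_channels, 1, rng=rng), nn.ReLU())
        for i, b in enumerate(self.branches):
            self._modules[f"branch{i}"] = b
        self.out_channels = mid_channels * (len(self.branches) + 1)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        n, c, h, w = x.shape
        outs = [b(x) for b in self.branches]
        pooled = self.pool_proj(nn.mean_axis(nn.mean_axis(x, 2), 3))
        outs.append(nn.broadcast_to(pooled, (n, self.pool_proj.layers[0].weight.shape[0], h, w)))
        return nn.concat(outs, axis=1)


# ---------------------------------------------------------------------------
# backbone and full model


class TinyBackbone(nn.Module):
    """4-stage strided encoder for desk-scale runs.

    Taps: low-level features at stride 4, high-level at ``output_stride``
    (16, or 8 by running the last stage undecimated with dilation 2).
    """

    def __init__(self, output_stride: int = 16, rng: np.random.Generator | None = None,
                 widths: tuple[int, int, int, int] = (16, 24, 32, 48)):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w1, w2, w3, w4 = widths
        self.stem = _conv_bn_relu(3, w1, 3, rng, stride=2)
        self.stage2 = nn.Sequential(
            nn.Conv2d(w1, w2, 3, stride=2, rng=rng), nn.BatchNorm2d(w2), nn.ReLU(),
            nn.Conv2d(w2, w2, 3, rng=rng), nn.BatchNorm2d(w2), nn.ReLU(),
        )
        self.stage3 = _conv_bn_relu(w2, w3, 3, rng, stride=2)
        if output_stride == 16:
            self.stage4 = _conv_bn_relu(w3, w4, 3, rng, stride=2)
        elif output_stride == 8:
            self.stage4 = _conv_bn_relu(w3, w4, 3, rng, dilation=2)
        else:
            raise ValueError("output_stride must be 8 or 16")
        self.low_channels = w2
        self.high_channels = w4

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        low = self.stage2(self.stem(x))
        high = self.stage4(self.stage3(low))
        return low, high


BACKBONES = {"tiny": TinyBackbone}


@dataclasses.dataclass
class SegModelConfig:
    n_classes: int
    backbone_name: str = "tiny"
    output_stride: int = 16
    denseaspp: DenseASPPConfig = dataclasses.field(default_factory=DenseASPPConfig)
    head: str = "denseaspp"          # "denseaspp" or "aspp" (the ablation axis)
    use_sp: bool = True
    sp_position: str = "before"      # gate before or after the pyramid head
    input_size: int = 64

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need background + at least one species")
        if self.output_stride not in (8, 16):
            raise ValueError("output_stride must be 8 or 16")
        if self.head not in ("denseaspp", "aspp"):
            raise ValueError("head must be 'denseaspp' or 'aspp'")
        if self.sp_position not in ("before", "after"):
            raise ValueError("sp_position must be 'before' or 'after'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SegModelConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "denseaspp" in d and isinstance(d["denseaspp"], dict):
            da = dict(d["denseaspp"])
            if "dilation_rates" in da:
                da["dilation_rates"] = tuple(da["dilation_rates"])
            d["denseaspp"] = DenseASPPConfig(**da)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["denseaspp"]["dilation_rates"] = list(d["denseaspp"]["dilation_rates"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


HEAD_CHANNELS = 64
LOW_PROJ_CHANNELS = 48  # DeepLabv3+ decoder convention


class SegModel(nn.Module):
    """Backbone -> (optional SP gate) -> pyramid head -> decoder -> scores."""

    def __init__(self, cfg: SegModelConfig, seed: int = 0):
        super().__init__()
        if cfg.backbone_name not in BACKBONES:
            raise ValueError(f"unknown backbone '{cfg.backbone_name}'; "
                             f"known: {sorted(BACKBONES)}")
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.backbone = BACKBONES[cfg.backbone_name](cfg.output_stride, rng=rng)
        high_c = self.backbone.high_channels
        if cfg.use_sp:
            self.sp = StripPooling(
                high_c if cfg.sp_position == "before" else HEAD_CHANNELS, rng=rng)
        if cfg.head == "denseaspp":
            self.pyramid = DenseASPP(high_c, cfg.denseaspp, rng=rng)
        else:
            self.pyramid = ASPP(high_c, cfg.denseaspp.dilation_rates,
                                cfg.denseaspp.mid_channels, rng=rng)
        self.project = _conv_bn_relu(self.pyramid.out_channels, HEAD_CHANNELS, 1, rng)
        self.low_proj = _conv_bn_relu(self.backbone.low_channels,
                                      LOW_PROJ_CHANNELS, 1, rng)
        self.refine = nn.Sequential(
            nn.Conv2d(HEAD_CHANNELS + LOW_PROJ_CHANNELS, HEAD_CHANNELS, 3, rng=rng),
            nn.BatchNorm2d(HEAD_CHANNELS), nn.ReLU(),
            nn.Conv2d(HEAD_CHANNELS, HEAD_CHANNELS, 3, rng=rng),
            nn.BatchNorm2d(HEAD_CHANNELS), nn.ReLU(),
        )
        self.classifier = nn.Conv2d(HEAD_CHANNELS, cfg.n_classes, 1, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        n, _, h, w = x.shape
        low, high = self.backbone(x)
        if self.cfg.use_sp and self.cfg.sp_position == "before":
            high = self.sp(high)
        feat = self.project(self.pyramid(high))
        if self.cfg.use_sp and self.cfg.sp_position == "after":
            feat = self.sp(feat)
        feat = nn.bilinear_resize(feat, low.shape[2], low.shape[3])
        feat = nn.concat([feat, self.low_proj(low)], axis=1)
        feat = self.refine(feat)
        logits = self.classifier(feat)
        return nn.bilinear_resize(logits, h, w)


def build_model(cfg: SegModelConfig, seed: int = 0) -> SegModel:
    return SegModel(cfg, seed=seed)


def save_checkpoint(model: SegModel, path: str | Path) -> None:
    state = model.named_state()
    state["__n_classes__"] = np.array(model.cfg.n_classes)
    np.savez(path, **state)


def load_checkpoint(model: SegModel, path: str | Path) -> SegModel:
    with np.load(path) as data:
        model.load_state({k: data[k] for k in data.files if not k.startswith("__")})
    return model
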