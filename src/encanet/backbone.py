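"""EfficientNet-B0..B3 feature extractors (classifier head removed).

The backbone is the standard compound-scaled MBConv stack: a strided stem,
seven stages of mobile inverted bottleneck blocks with squeeze-excitation,
and a final 1x1 expansion.  Channel widths are rounded to multiples of 8 and
stage depths are ceil-scaled, following the reference scaling rules, so the
trainable-parameter counts match the reference models exactly (e.g. the B0
feature stack has 4,007,548 parameters).  A 416x416 input yields a single
stride-32 map of 13x13.

Weights are randomly initialized; a state dict trained elsewhere can be
loaded through :meth:`~encanet.nnops.layers.Module.load_state_dict`.
"""

from __future__ import annotations

import math

import numpy as np

from .nnops import BatchNorm2d, Conv2d, Module, Sequential, SiLU

# (expand_ratio, kernel, stride, in_channels, out_channels, layers) at B0 scale
_STAGES = (
    (1, 3, 1, 32, 16, 1),
    (6, 3, 2, 16, 24, 2),
    (6, 5, 2, 24, 40, 2),
    (6, 3, 2, 40, 80, 3),
    (6, 5, 1, 80, 112, 3),
    (6, 5, 2, 112, 192, 4),
    (6, 3, 1, 192, 320, 1),
)

# (width multiplier, depth multiplier)
_SCALING = {"b0": (1.0, 1.0), "b1": (1.0, 1.1), "b2": (1.1, 1.2), "b3": (1.2, 1.4)}

VARIANTS = tuple(_SCALING)


def _round_channels(channels: float, divisor: int = 8) -> int:
    """Round to the nearest multiple of `divisor`, never dropping below 90%."""
    rounded = max(divisor, int(channels + divisor / 2) // divisor * divisor)
    if rounded < 0.9 * channels:
        rounded += divisor
    return rounded


def backbone_output_channels(variant: str) -> int:
    width, _ = _scaling(variant)
    return 4 * _round_channels(320 * width)


def _scaling(variant: str):
    if variant not in _SCALING:
        raise ValueError(f"unknown backbone variant {variant!r}; expected one of {VARIANTS}")
    return _SCALING[variant]


class SqueezeExcite(Module):
    """In-block SE gate with squeeze width = block input channels // 4."""

    def __init__(self, channels: int, squeeze: int, rng):
        super().__init__()
        self.fc1 = Conv2d(channels, squeeze, 1, bias=True, rng=rng)
        self.fc2 = Conv2d(squeeze, channels, 1, bias=True, rng=rng)

    def forward(self, x):
        s = x.mean(axis=(2, 3), keepdims=True)
        s = self.fc2(self.fc1(s).silu()).sigmoid()
        return x * s


class MBConv(Module):
    def __init__(self, c_in, c_out, expand_ratio, kernel, stride, squeeze, rng):
        super().__init__()
        c_exp = _round_channels(c_in * expand_ratio)
        self.use_residual = stride == 1 and c_in == c_out
        layers = []
        if c_exp != c_in:
            layers += [Conv2d(c_in, c_exp, 1, bias=False, rng=rng),
                       BatchNorm2d(c_exp), SiLU()]
        layers += [Conv2d(c_exp, c_exp, kernel, stride=stride,
                          padding=(kernel - 1) // 2, groups=c_exp, bias=False, rng=rng),
                   BatchNorm2d(c_exp), SiLU(),
                   SqueezeExcite(c_exp, squeeze, rng),
                   Conv2d(c_exp, c_out, 1, bias=False, rng=rng),
                   BatchNorm2d(c_out)]
        self.block = Sequential(*layers)

    def forward(self, x):
        y = self.block(x)
        return x + y if self.use_residual else y


class EfficientNetFeatures(Module):
    """Stem through the final 1x1 expansion; emits one stride-32 feature map."""

    def __init__(self, variant: str = "b0", rng=None):
        super().__init__()
        width, depth = _scaling(variant)
        rng = rng or np.random.default_rng(0)
        self.variant = variant

        stem_out = _round_channels(32 * width)
        self.stem = Sequential(
            Conv2d(3, stem_out, 3, stride=2, padding=1, bias=False, rng=rng),
            BatchNorm2d(stem_out), SiLU())

        blocks = []
        for expand, kernel, stride, c_in, c_out, layers in _STAGES:
            c_in = _round_channels(c_in * width)
            c_out = _round_channels(c_out * width)
            for i in range(int(math.ceil(layers * depth))):
                block_in = c_in if i == 0 else c_out
                squeeze = max(1, block_in // 4)
                blocks.append(MBConv(block_in, c_out, expand, kernel,
                                     stride if i == 0 else 1, squeeze, rng))
        self.blocks = Sequential(*blocks)

        head_out = 4 * c_out
        self.head = Sequential(
            Conv2d(c_out, head_out, 1, bias=False, rng=rng),
            BatchNorm2d(head_out), SiLU())
        self.out_channels = head_out

    def forward(self, x):
        return self.head(self.blocks(self.stem(x)))


def build_backbone(variant: str = "b0", rng=None) -> EfficientNetFeatures:
    """Feature extractor for one of the B0..B3 compound-scaled variants."""
    return EfficientNetFeatures(variant, rng=rng)
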