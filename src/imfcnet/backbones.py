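"""ImageNet-topology feature extractors.

Both families are built from their published definitions, truncated before
global average pooling: Inception-V3 (Szegedy et al.) maps a 299x299x3 image
to an 8x8x2048 feature map; MobileNet-V2 (Sandler et al.) maps 224x224x3 to
7x7x1280.  The layers after the terminal map (global pooling and the
1000-class ImageNet head) are absent.

Convolution layers carry biases in addition to the batch-norm shift, the
convention of the MATLAB deep-learning stack; pass ``conv_bias=False`` for
the bias-free convention used by torch-style definitions.  ``width_mult``
and ``input_size`` are extension hooks for reduced-scale experiments; the
canonical configurations are ``width_mult=1.0`` at the default input sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F

INCEPTION_V3_INPUT = (299, 299, 3)
INCEPTION_V3_TERMINAL = (8, 8, 2048)
MOBILENET_V2_INPUT = (224, 224, 3)
MOBILENET_V2_TERMINAL = (7, 7, 1280)

_DEFAULTS = {
    "inception_v3": (INCEPTION_V3_INPUT, INCEPTION_V3_TERMINAL),
    "mobilenet_v2": (MOBILENET_V2_INPUT, MOBILENET_V2_TERMINAL),
}


class ConfigurationError(ValueError):
    """Invalid network specification."""


class WeightsUnavailableError(RuntimeError):
    """Pretrained weights were requested but no weight source exists."""


@dataclass
class BackboneSpec:
    """Declarative description of a truncated feature extractor.

    ``input_shape`` / ``terminal_shape`` are (height, width, channels); they
    default to the family's canonical values and are recomputed when
    ``input_size`` or ``width_mult`` deviate from the defaults.
    """

    family: str = "inception_v3"
    pretrained: bool = False
    weights_path: str | None = None
    width_mult: float = 1.0
    input_size: int | None = None
    conv_bias: bool = True
    seed: int = 0
    input_shape: tuple[int, int, int] = field(default=None)  # type: ignore
    terminal_shape: tuple[int, int, int] = field(default=None)  # type: ignore

    def __post_init__(self):
        if self.family not in _DEFAULTS:
            raise ConfigurationError(
                f"unknown backbone family {self.family!r}; "
                f"supported: {sorted(_DEFAULTS)}")
        default_in, default_term = _DEFAULTS[self.family]
        size = self.input_size or default_in[0]
        if self.input_shape is None:
            self.input_shape = (size, size, 3)
        if self.terminal_shape is None:
            if size == default_in[0] and self.width_mult == 1.0:
                self.terminal_shape = default_term
            else:
                self.terminal_shape = _infer_terminal(self)


def _round_channels(c: int, width_mult: float) -> int:
    """Standard divisible-by-8 channel rounding used by width multipliers."""
    if width_mult == 1.0:
        return c
    v = max(8, int(c * width_mult + 4) // 8 * 8)
    if v < 0.9 * c * width_mult:
        v += 8
    return v


# ---------------------------------------------------------------------------
# Inception-V3
# ---------------------------------------------------------------------------

class _ConvBNReLU(nn.Module):
    """conv -> batch norm -> ReLU, the basic Inception unit."""

    def __init__(self, cin, cout, kernel, stride=1, padding=0, bias=True,
                 rng=None, relu6=False):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, kernel, stride, padding,
                              bias=bias, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.ReLU6() if relu6 else nn.ReLU()
        self.out_channels = cout

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class _InceptionA(nn.Module):
    def __init__(self, cin, pool_features, c, bias, rng):
        super().__init__()
        self.b1x1 = _ConvBNReLU(cin, c(64), 1, bias=bias, rng=rng)
        self.b5x5_1 = _ConvBNReLU(cin, c(48), 1, bias=bias, rng=rng)
        self.b5x5_2 = _ConvBNReLU(c(48), c(64), 5, padding=2, bias=bias, rng=rng)
        self.b3x3_1 = _ConvBNReLU(cin, c(64), 1, bias=bias, rng=rng)
        self.b3x3_2 = _ConvBNReLU(c(64), c(96), 3, padding=1, bias=bias, rng=rng)
        self.b3x3_3 = _ConvBNReLU(c(96), c(96), 3, padding=1, bias=bias, rng=rng)
        self.bpool = _ConvBNReLU(cin, c(pool_features), 1, bias=bias, rng=rng)
        self.out_channels = c(64) + c(64) + c(96) + c(pool_features)

    def forward(self, x):
        return F.concat([
            self.b1x1(x),
            self.b5x5_2(self.b5x5_1(x)),
            self.b3x3_3(self.b3x3_2(self.b3x3_1(x))),
            self.bpool(F.avg_pool2d(x, 3, 1, 1)),
        ])


class _InceptionB(nn.Module):
    """35x35 -> 17x17 grid reduction."""

    def __init__(self, cin, c, bias, rng):
        super().__init__()
        self.b3x3 = _ConvBNReLU(cin, c(384), 3, stride=2, bias=bias, rng=rng)
        self.b3x3dbl_1 = _ConvBNReLU(cin, c(64), 1, bias=bias, rng=rng)
        self.b3x3dbl_2 = _ConvBNReLU(c(64), c(96), 3, padding=1, bias=bias, rng=rng)
        self.b3x3dbl_3 = _ConvBNReLU(c(96), c(96), 3, stride=2, bias=bias, rng=rng)
        self.out_channels = c(384) + c(96) + cin

    def forward(self, x):
        return F.concat([
            self.b3x3(x),
            self.b3x3dbl_3(self.b3x3dbl_2(self.b3x3dbl_1(x))),
            F.max_pool2d(x, 3, 2),
        ])


class _InceptionC(nn.Module):
    """17x17 factorized 7x7 module."""

    def __init__(self, cin, c7, c, bias, rng):
        super().__init__()
        k = dict(bias=bias, rng=rng)
        self.b1x1 = _ConvBNReLU(cin, c(192), 1, **k)
        self.b7_1 = _ConvBNReLU(cin, c(c7), 1, **k)
        self.b7_2 = _ConvBNReLU(c(c7), c(c7), (1, 7), padding=(0, 3), **k)
        self.b7_3 = _ConvBNReLU(c(c7), c(192), (7, 1), padding=(3, 0), **k)
        self.b7dbl_1 = _ConvBNReLU(cin, c(c7), 1, **k)
        self.b7dbl_2 = _ConvBNReLU(c(c7), c(c7), (7, 1), padding=(3, 0), **k)
        self.b7dbl_3 = _ConvBNReLU(c(c7), c(c7), (1, 7), padding=(0, 3), **k)
        self.b7dbl_4 = _ConvBNReLU(c(c7), c(c7), (7, 1), padding=(3, 0), **k)
        self.b7dbl_5 = _ConvBNReLU(c(c7), c(192), (1, 7), padding=(0, 3), **k)
        self.bpool = _ConvBNReLU(cin, c(192), 1, **k)
        self.out_channels = 4 * c(192)

    def forward(self, x):
        return F.concat([
            self.b1x1(x),
            self.b7_3(self.b7_2(self.b7_1(x))),
            self.b7dbl_5(self.b7dbl_4(self.b7dbl_3(self.b7dbl_2(self.b7dbl_1(x))))),
            self.bpool(F.avg_pool2d(x, 3, 1, 1)),
        ])


class _InceptionD(nn.Module):
    """17x17 -> 8x8 grid reduction."""

    def __init__(self, cin, c, bias, rng):
        super().__init__()
        k = dict(bias=bias, rng=rng)
        self.b3x3_1 = _ConvBNReLU(cin, c(192), 1, **k)
        self.b3x3_2 = _ConvBNReLU(c(192), c(320), 3, stride=2, **k)
        self.b7x7_1 = _ConvBNReLU(cin, c(192), 1, **k)
        self.b7x7_2 = _ConvBNReLU(c(192), c(192), (1, 7), padding=(0, 3), **k)
        self.b7x7_3 = _ConvBNReLU(c(192), c(192), (7, 1), padding=(3, 0), **k)
        self.b7x7_4 = _ConvBNReLU(c(192), c(192), 3, stride=2, **k)
        self.out_channels = c(320) + c(192) + cin

    def forward(self, x):
        return F.concat([
            self.b3x3_2(self.b3x3_1(x)),
            self.b7x7_4(self.b7x7_3(self.b7x7_2(self.b7x7_1(x)))),
            F.max_pool2d(x, 3, 2),
        ])


class _InceptionE(nn.Module):
    """8x8 module with expanded-filter-bank branches."""

    def __init__(self, cin, c, bias, rng):
        super().__init__()
        k = dict(bias=bias, rng=rng)
        self.b1x1 = _ConvBNReLU(cin, c(320), 1, **k)
        self.b3x3_1 = _ConvBNReLU(cin, c(384), 1, **k)
        self.b3x3_2a = _ConvBNReLU(c(384), c(384), (1, 3), padding=(0, 1), **k)
        self.b3x3_2b = _ConvBNReLU(c(384), c(384), (3, 1), padding=(1, 0), **k)
        self.b3x3dbl_1 = _ConvBNReLU(cin, c(448), 1, **k)
        self.b3x3dbl_2 = _ConvBNReLU(c(448), c(384), 3, padding=1, **k)
        self.b3x3dbl_3a = _ConvBNReLU(c(384), c(384), (1, 3), padding=(0, 1), **k)
        self.b3x3dbl_3b = _ConvBNReLU(c(384), c(384), (3, 1), padding=(1, 0), **k)
        self.bpool = _ConvBNReLU(cin, c(192), 1, **k)
        self.out_channels = c(320) + 2 * c(384) + 2 * c(384) + c(192)

    def forward(self, x):
        b3 = self.b3x3_1(x)
        b3d = self.b3x3dbl_2(self.b3x3dbl_1(x))
        return F.concat([
            self.b1x1(x),
            F.concat([self.b3x3_2a(b3), self.b3x3_2b(b3)]),
            F.concat([self.b3x3dbl_3a(b3d), self.b3x3dbl_3b(b3d)]),
            self.bpool(F.avg_pool2d(x, 3, 1, 1)),
        ])


class InceptionV3Features(nn.Module):
    """Inception-V3 truncated before global average pooling.

    The interpretability registry groups the modules into five blocks:
    A = stem convolutions, B = the three 35x35 modules, C = the 17x17
    stage, D = the second grid reduction, E = the two 8x8 modules.
    """

    def __init__(self, width_mult: float = 1.0, conv_bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c = lambda v: _round_channels(v, width_mult)  # noqa: E731
        k = dict(bias=conv_bias, rng=rng)
        self.stem = nn.Sequential(
            _ConvBNReLU(3, c(32), 3, stride=2, **k),
            _ConvBNReLU(c(32), c(32), 3, **k),
            _ConvBNReLU(c(32), c(64), 3, padding=1, **k),
            nn.MaxPool2d(3, 2),
            _ConvBNReLU(c(64), c(80), 1, **k),
            _ConvBNReLU(c(80), c(192), 3, **k),
            nn.MaxPool2d(3, 2),
        )
        self.mixed_5b = _InceptionA(c(192), 32, c, conv_bias, rng)
        self.mixed_5c = _InceptionA(self.mixed_5b.out_channels, 64, c, conv_bias, rng)
        self.mixed_5d = _InceptionA(self.mixed_5c.out_channels, 64, c, conv_bias, rng)
        self.mixed_6a = _InceptionB(self.mixed_5d.out_channels, c, conv_bias, rng)
        self.mixed_6b = _InceptionC(self.mixed_6a.out_channels, 128, c, conv_bias, rng)
        self.mixed_6c = _InceptionC(self.mixed_6b.out_channels, 160, c, conv_bias, rng)
        self.mixed_6d = _InceptionC(self.mixed_6c.out_channels, 160, c, conv_bias, rng)
        self.mixed_6e = _InceptionC(self.mixed_6d.out_channels, 192, c, conv_bias, rng)
        self.mixed_7a = _InceptionD(self.mixed_6e.out_channels, c, conv_bias, rng)
        self.mixed_7b = _InceptionE(self.mixed_7a.out_channels, c, conv_bias, rng)
        self.mixed_7c = _InceptionE(self.mixed_7b.out_channels, c, conv_bias, rng)
        self.out_channels = self.mixed_7c.out_channels

    def forward(self, x):
        x = self.stem(x)
        x = self.mixed_5d(self.mixed_5c(self.mixed_5b(x)))
        x = self.mixed_6a(x)
        x = self.mixed_6e(self.mixed_6d(self.mixed_6c(self.mixed_6b(x))))
        x = self.mixed_7a(x)
        return self.mixed_7c(self.mixed_7b(x))


# ---------------------------------------------------------------------------
# MobileNet-V2
# ---------------------------------------------------------------------------

# (expansion t, output channels c, repeats n, first stride s)
_MOBILENET_V2_CFG = [
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
]


class _InvertedResidual(nn.Module):
    """Expand (1x1) -> depthwise 3x3 -> project (1x1), residual when the
    block keeps resolution and channel count."""

    def __init__(self, cin, cout, stride, expand, bias, rng):
        super().__init__()
        hidden = cin * expand
        self.use_residual = stride == 1 and cin == cout
        if expand != 1:
            self.expand = _ConvBNReLU(cin, hidden, 1, bias=bias, rng=rng,
                                      relu6=True)
        else:
            self.expand = None
        self.dw = nn.DepthwiseConv2d(hidden, 3, stride, 1, bias=bias, rng=rng)
        self.dw_bn = nn.BatchNorm2d(hidden)
        self.dw_act = nn.ReLU6()
        self.project = nn.Conv2d(hidden, cout, 1, bias=bias, rng=rng)
        self.project_bn = nn.BatchNorm2d(cout)
        self.out_channels = cout

    def forward(self, x):
        y = self.expand(x) if self.expand is not None else x
        y = self.dw_act(self.dw_bn(self.dw(y)))
        y = self.project_bn(self.project(y))
        return F.add(y, x) if self.use_residual else y


class MobileNetV2Features(nn.Module):
    """MobileNet-V2 truncated before global average pooling.

    Blocks follow the published inverted-residual stack; ``blocks[i]`` are
    the bottleneck ("Block B") modules, the stem and the final 1x1 expansion
    are the plain-convolution ("Block A") layers.
    """

    def __init__(self, width_mult: float = 1.0, conv_bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c = lambda v: _round_channels(v, width_mult)  # noqa: E731
        cin = c(32)
        self.stem = _ConvBNReLU(3, cin, 3, stride=2, padding=1,
                                bias=conv_bias, rng=rng, relu6=True)
        blocks = []
        for t, ch, n, s in _MOBILENET_V2_CFG:
            cout = c(ch)
            for i in range(n):
                blocks.append(_InvertedResidual(
                    cin, cout, s if i == 0 else 1, t, conv_bias, rng))
                cin = cout
        self.blocks = nn.Sequential(*blocks)
        last = c(1280) if width_mult > 1.0 else (
            1280 if width_mult == 1.0 else _round_channels(1280, width_mult))
        self.head_conv = _ConvBNReLU(cin, last, 1, bias=conv_bias, rng=rng,
                                     relu6=True)
        self.out_channels = last

    def forward(self, x):
        return self.head_conv(self.blocks(self.stem(x)))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _build_raw(spec: BackboneSpec) -> nn.Module:
    rng = np.random.default_rng(spec.seed)
    if spec.family == "inception_v3":
        return InceptionV3Features(spec.width_mult, spec.conv_bias, rng)
    return MobileNetV2Features(spec.width_mult, spec.conv_bias, rng)


def _infer_terminal(spec: BackboneSpec) -> tuple[int, int, int]:
    """Probe the terminal map shape by a forward pass on a zero input."""
    net = _build_raw(spec)
    net.eval()
    size = spec.input_size or _DEFAULTS[spec.family][0][0]
    with nn.no_grad():
        out = net(nn.Tensor(np.zeros((1, 3, size, size), np.float32)))
    return (out.shape[2], out.shape[3], out.shape[1])


def build_backbone(spec: BackboneSpec) -> nn.Module:
    """Construct the truncated feature extractor described by ``spec``.

    Raises :class:`WeightsUnavailableError` if ``pretrained`` is set and no
    ``weights_path`` is given: random initialization must be requested
    explicitly (``pretrained=False``), never silently substituted.
    """
    net = _build_raw(spec)
    if spec.pretrained:
        if not spec.weights_path:
            raise WeightsUnavailableError(
                "pretrained weights requested but no weights_path is set; "
                "either provide a checkpoint (npz state dict) or opt in to "
                "random initialization with pretrained=False")
        net.load(spec.weights_path)
    net.input_shape = spec.input_shape
    net.terminal_shape = spec.terminal_shape
    return net


def summary(module: nn.Module) -> str:
    """Plain-text per-parameter summary (name, shape, count)."""
    lines = [f"{'parameter':60s} {'shape':>20s} {'count':>12s}"]
    for name, p in module.named_parameters():
        lines.append(f"{name:60s} {str(p.data.shape):>20s} {p.size:>12,d}")
    lines.append(f"{'total trainable':60s} {'':>20s} "
                 f"{nn.count_parameters(module):>12,d}")
    return "\n".join(lines)


count_parameters = nn.count_parameters
format_millions = nn.format_millions
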