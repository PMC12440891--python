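"""Neural building blocks for lightweight crop/weed segmentation.

Each block is testable in isolation:

* :class:`DSDConv` — depthwise separable *dilated* convolution: every input
  channel is convolved independently with a dilated k×k kernel, then a 1×1
  pointwise convolution mixes channels.  For a 3×3 layer this replaces
  ``9·C_in·C_out`` multiply–accumulates per pixel with ``9·C_in + C_in·C_out``.
* :class:`InvertedResidual` — the MobileNetV2 expand → depthwise → linear-project
  bottleneck, with a skip connection when stride is 1 and the channel count is
  preserved.
* :class:`StripPooling` — row-wise and column-wise average pooling producing
  directional context profiles.  Each profile passes a depthwise 1-D
  convolution, the two are broadcast-summed into an H×W map ``y``, and the
  input is gated: ``z = x ⊙ σ(f(y))``.
* :class:`ChannelAttention` / :class:`SpatialAttention` / :class:`CBAM` —
  channel gate ``M_c = σ(ω(max-pool) + ω(avg-pool))`` with a shared two-layer
  perceptron ω, spatial gate from a 7×7 convolution over the concatenated
  channel-mean/channel-max maps, and their sequential composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import autograd as ag

__all__ = [
    "BlockSpec",
    "ConvBNAct",
    "DSDConv",
    "InvertedResidual",
    "StripPooling",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "dsd_conv_param_count",
    "standard_conv_param_count",
]


@dataclass(frozen=True)
class BlockSpec:
    """Shape/stride contract of a convolutional block.

    ``expansion`` is the inverted-residual widening factor t; ``repeats``
    the number of times the block is stacked within a stage.
    """

    in_channels: int
    out_channels: int
    kernel: int = 3
    stride: int = 1
    dilation: int = 1
    expansion: int = 1
    repeats: int = 1

    def __post_init__(self):
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")
        if self.expansion < 1:
            raise ValueError("expansion factor must be >= 1")
        if min(self.in_channels, self.out_channels, self.repeats) < 1:
            raise ValueError("channel counts and repeats must be positive")


def dsd_conv_param_count(in_channels: int, out_channels: int, kernel: int = 3) -> int:
    """Weight count of the depthwise+pointwise factorization (convs only)."""
    return in_channels * kernel * kernel + in_channels * out_channels


def standard_conv_param_count(in_channels: int, out_channels: int, kernel: int = 3) -> int:
    """Weight count of the equivalent dense convolution (convs only)."""
    return kernel * kernel * in_channels * out_channels


class ConvBNAct(nn.Module):
    """Convolution → batch norm → optional activation."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 1,
        stride: int = 1,
        dilation: int = 1,
        groups: int = 1,
        activation: str | None = "relu",
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        kh = kernel if np.isscalar(kernel) else kernel[0]
        kw = kernel if np.isscalar(kernel) else kernel[1]
        padding = (dilation * (kh - 1) // 2, dilation * (kw - 1) // 2)
        self.conv = nn.Conv2d(
            in_channels,
            out_channels,
            kernel,
            stride=stride,
            padding=padding,
            dilation=dilation,
            groups=groups,
            bias=False,
            rng=rng,
        )
        self.bn = nn.BatchNorm2d(out_channels)
        if activation is None:
            self.act = nn.Identity()
        elif activation == "relu":
            self.act = nn.ReLU()
        elif activation == "relu6":
            self.act = nn.ReLU6()
        else:
            raise ValueError(f"unknown activation {activation!r}")

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class DSDConv(nn.Module):
    """Depthwise separable dilated convolution.

    With ``norm=False`` and ``activation=None`` the block is purely linear:
    a per-channel dilated k×k convolution followed by 1×1 channel mixing,
    exactly the factorization checked by the dense-convolution oracle tests.
    Model code uses the normalized variant (batch norm after each of the two
    convolutions, activation after each norm).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        dilation: int = 1,
        norm: bool = True,
        activation: str | None = "relu",
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        self.spec = BlockSpec(in_channels, out_channels, kernel, stride, dilation)
        padding = dilation * (kernel - 1) // 2
        if norm:
            self.depthwise = ConvBNAct(
                in_channels,
                in_channels,
                kernel,
                stride=stride,
                dilation=dilation,
                groups=in_channels,
                activation=activation,
                rng=rng,
            )
            self.pointwise = ConvBNAct(
                in_channels, out_channels, 1, activation=activation, rng=rng
            )
        else:
            self.depthwise = nn.Conv2d(
                in_channels,
                in_channels,
                kernel,
                stride=stride,
                padding=padding,
                dilation=dilation,
                groups=in_channels,
                bias=False,
                rng=rng,
            )
            self.pointwise = nn.Conv2d(
                in_channels, out_channels, 1, bias=False, rng=rng
            )

    def forward(self, x):
        return self.pointwise(self.depthwise(x))


class InvertedResidual(nn.Module):
    """MobileNetV2 inverted residual with linear bottleneck.

    A 1×1 expansion (skipped when t = 1) widens the channel count by t with
    ReLU6, a depthwise 3×3 at the given stride/dilation follows, and a 1×1
    projection maps back down with *no* nonlinearity.  The residual skip is
    applied only when stride is 1 and input/output channels match.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: int = 1,
        expansion: int = 6,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.spec = BlockSpec(
            in_channels, out_channels, 3, stride, dilation, expansion
        )
        hidden = in_channels * expansion
        self.use_residual = stride == 1 and in_channels == out_channels
        if expansion != 1:
            self.expand = ConvBNAct(
                in_channels, hidden, 1, activation="relu6", rng=rng
            )
        else:
            self.expand = nn.Identity()
        self.depthwise = ConvBNAct(
            hidden,
            hidden,
            3,
            stride=stride,
            dilation=dilation,
            groups=hidden,
            activation="relu6",
            rng=rng,
        )
        self.project = ConvBNAct(hidden, out_channels, 1, activation=None, rng=rng)

    def forward(self, x):
        out = self.project(self.depthwise(self.expand(x)))
        if self.use_residual:
            out = ag.add(out, x)
        return out


class StripPooling(nn.Module):
    """Row/column strip pooling gate.

    ``y^h_i = (1/W) Σ_j x_{i,j}`` and ``y^v_j = (1/H) Σ_i x_{i,j}`` are the
    horizontal and vertical context profiles.  Each passes a depthwise 1-D
    convolution (kernel 3) along its own axis, the results are broadcast back
    to H×W and summed, ``y_{c,i,j} = conv(y^h)_{c,i} + conv(y^v)_{c,j}``, and
    a depthwise 1×1 fusion convolution f feeds the logistic gate:
    ``z = x ⊙ σ(f(y))``.  All convolutions are channel-preserving; the module
    keeps the block lightweight by avoiding any channel mixing.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        self.conv_h = ConvBNAct(
            channels, channels, (3, 1), groups=channels, activation=None, rng=rng
        )
        self.conv_v = ConvBNAct(
            channels, channels, (1, 3), groups=channels, activation=None, rng=rng
        )
        self.fuse = ConvBNAct(
            channels, channels, 1, groups=channels, activation=None, rng=rng
        )

    def forward(self, x):
        _, _, h, w = x.shape
        if h < 1 or w < 1:
            raise ValueError("strip pooling requires non-empty spatial dims")
        yh = ag.mean(x, axis=3, keepdims=True)  # (N, C, H, 1)
        yv = ag.mean(x, axis=2, keepdims=True)  # (N, C, 1, W)
        y = ag.add(self.conv_h(yh), self.conv_v(yv))  # broadcast to (N, C, H, W)
        gate = ag.sigmoid(self.fuse(y))
        return ag.mul(x, gate)


class ChannelAttention(nn.Module):
    """Channel gate ``M_c(F) = σ(ω F^c_max + ω F^c_avg)``.

    ω is a shared two-layer perceptron (no biases) with hidden width
    ``max(1, C // reduction)`` and ReLU in between.
    """

    def __init__(
        self,
        channels: int,
        reduction: int = 16,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if channels >= reduction and channels % reduction != 0:
            raise ValueError("channels must be divisible by the reduction ratio")
        hidden = max(1, channels // reduction)
        self.channels = channels
        self.fc1 = nn.Linear(channels, hidden, bias=False, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, bias=False, rng=rng)

    def _mlp(self, v):
        return self.fc2(ag.relu(self.fc1(v)))

    def forward(self, x):
        n, c, _, _ = x.shape
        avg = ag.reshape(ag.mean(x, axis=(2, 3), keepdims=False), (n, c))
        mx = ag.reshape(ag.amax(x, axis=(2, 3), keepdims=False), (n, c))
        gate = ag.sigmoid(ag.add(self._mlp(mx), self._mlp(avg)))
        return ag.reshape(gate, (n, c, 1, 1))


class SpatialAttention(nn.Module):
    """Spatial gate from channel-mean and channel-max maps.

    The two 1×H×W maps are concatenated and convolved with a single k×k
    kernel (default 7, padding k//2), then squashed with σ.
    """

    def __init__(self, kernel: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        self.conv = nn.Conv2d(
            2, 1, kernel, padding=kernel // 2, bias=True, rng=rng
        )

    def forward(self, x):
        avg = ag.mean(x, axis=1, keepdims=True)
        mx = ag.amax(x, axis=1, keepdims=True)
        return ag.sigmoid(self.conv(ag.concat([avg, mx], axis=1)))


class CBAM(nn.Module):
    """Sequential channel-then-spatial attention: ``M_s(G) ⊙ G`` with
    ``G = M_c(F) ⊙ F``.  Both gates lie strictly in (0, 1), so the output is
    element-wise bounded by the input."""

    def __init__(
        self,
        channels: int,
        reduction: int = 16,
        spatial_kernel: int = 7,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(spatial_kernel, rng=rng)

    def forward(self, x):
        g = ag.mul(x, self.channel(x))
        return ag.mul(g, self.spatial(g))
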