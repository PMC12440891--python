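"""MobileNetV2 feature extractor.

The stage table is the stock MobileNetV2 layout (width multiplier 1.0):

====== ========== === ==== === ===
input  operator    t   c    n   s
====== ========== === ==== === ===
512²×3   conv2d        32   1   2
256²×32  bottleneck 1  16   1   1
256²×16  bottleneck 6  24   2   2
128²×24  bottleneck 6  32   3   2
64²×32   bottleneck 6  64   4   2
32²×64   bottleneck 6  96   3   1
32²×96   bottleneck 6  160  3   2
16²×160  bottleneck 6  320  1   1
16²×320  conv2d        1280 1   1
====== ========== === ==== === ===

In *classification* mode the net realizes every row including the final
1280-channel 1×1 convolution, global average pool and classifier.  In
*segmentation* mode those three are dropped and, at output stride 16, the
stride-2 entry of the 160-channel stage is converted to stride 1 with
dilation 2 in the subsequent depthwise kernels, so the deepest features stay
at 1/16 resolution for the spatial pyramid.  Multi-resolution taps are taken
at the 24- (1/4), 32- (1/8), 96- (1/16) and 320-channel (1/16) stage outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .blocks import BlockSpec, ConvBNAct, InvertedResidual
from .nn import Tensor

__all__ = [
    "MOBILENETV2_STAGES",
    "BackboneConfig",
    "BackboneFeatures",
    "MobileNetV2",
    "build_backbone",
]

# (expansion t, out channels c, repeats n, first stride s) per bottleneck stage
MOBILENETV2_STAGES: tuple[tuple[int, int, int, int], ...] = (
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
)

# stage index (into MOBILENETV2_STAGES) -> feature tap name
_TAPS = {1: "os4", 2: "os8", 4: "os16_mid", 6: "os16_deep"}


@dataclass(frozen=True)
class BackboneConfig:
    mode: str = "segmentation"  # "classification" | "segmentation"
    output_stride: int = 16  # segmentation only: 16 or 32
    num_classes: int = 1000  # classification head size
    stem_channels: int = 32
    last_channels: int = 1280
    stages: tuple[tuple[int, int, int, int], ...] = MOBILENETV2_STAGES

    def __post_init__(self):
        if self.mode not in ("classification", "segmentation"):
            raise ValueError(f"unknown backbone mode {self.mode!r}")
        if self.output_stride not in (16, 32):
            raise ValueError("output_stride must be 16 or 32")


@dataclass
class BackboneFeatures:
    """Multi-resolution taps: strides 4 / 8 / 16 / 16 with 24/32/96/320 ch."""

    os4: Tensor
    os8: Tensor
    os16_mid: Tensor
    os16_deep: Tensor


class MobileNetV2(nn.Module):
    def __init__(self, cfg: BackboneConfig | None = None, rng=None):
        super().__init__()
        self.cfg = cfg or BackboneConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        seg = self.cfg.mode == "segmentation"
        self._frozen = False

        self.stem = ConvBNAct(3, self.cfg.stem_channels, 3, stride=2,
                              activation="relu6", rng=rng)
        self.stages = nn.Sequential()
        in_ch = self.cfg.stem_channels
        current_stride = 2
        dilation = 1
        self._stage_specs: list[BlockSpec] = []
        for t, c, n, s in self.cfg.stages:
            blocks = nn.Sequential()
            for i in range(n):
                stride = s if i == 0 else 1
                block_dilation = dilation
                if (
                    seg
                    and stride == 2
                    and current_stride >= self.cfg.output_stride
                ):
                    # dilation trick: keep resolution, grow receptive field
                    stride = 1
                    dilation *= 2
                elif stride == 2:
                    current_stride *= 2
                blocks.append(
                    InvertedResidual(
                        in_ch, c, stride=stride, expansion=t,
                        dilation=block_dilation, rng=rng,
                    )
                )
                self._stage_specs.append(
                    BlockSpec(in_ch, c, 3, stride, block_dilation, t, 1)
                )
                in_ch = c
            self.stages.append(blocks)
        self.out_channels = in_ch

        if self.cfg.mode == "classification":
            self.head_conv = ConvBNAct(in_ch, self.cfg.last_channels, 1,
                                       activation="relu6", rng=rng)
            self.pool = nn.GlobalAvgPool2d()
            self.classifier = nn.Linear(
                self.cfg.last_channels, self.cfg.num_classes, rng=rng
            )

    # -- freeze/unfreeze -----------------------------------------------------

    def set_frozen(self, frozen: bool) -> None:
        """Freeze (or resume) backbone updates.

        Frozen weights receive no gradient and batch-norm running statistics
        stop updating; toggling back resumes training from the current state.
        """
        self._frozen = bool(frozen)
        self.requires_grad_(not frozen)
        if frozen:
            nn.Module.train(self, False)
        elif self.training:
            nn.Module.train(self, True)

    def train(self, mode: bool = True):
        # a frozen backbone stays in inference mode (no BN stat updates)
        return nn.Module.train(self, mode and not self._frozen)

    # -- forward -------------------------------------------------------------

    def _check_input(self, image: Tensor) -> None:
        if image.ndim != 4 or image.shape[1] != 3:
            raise ValueError("expected an (N, 3, H, W) image batch")
        _, _, h, w = image.shape
        if h % 16 or w % 16:
            raise ValueError("input height and width must be divisible by 16")

    def forward_features(self, image: Tensor) -> BackboneFeatures:
        self._check_input(image)
        x = self.stem(image)
        taps = {}
        for i, stage in enumerate(self.stages):
            x = stage(x)
            if i in _TAPS:
                taps[_TAPS[i]] = x
        return BackboneFeatures(**taps)

    def forward(self, image: Tensor) -> Tensor:
        if self.cfg.mode == "segmentation":
            return self.forward_features(image).os16_deep
        self._check_input(image)
        x = self.stem(image)
        for stage in self.stages:
            x = stage(x)
        x = self.pool(self.head_conv(x))
        n, c = x.shape[0], x.shape[1]
        return self.classifier(x.reshape(n, c))

    def stage_output_shapes(self, input_hw: tuple[int, int]) -> list[tuple]:
        """(N=1) output shape after each table row, by a real forward pass."""
        h, w = input_hw
        shapes = []
        with nn.no_grad():
            was_training = self.training
            nn.Module.train(self, False)
            x = self.stem(Tensor(np.zeros((1, 3, h, w), np.float32)))
            shapes.append(x.shape)
            for stage in self.stages:
                x = stage(x)
                shapes.append(x.shape)
            if self.cfg.mode == "classification":
                x = self.head_conv(x)
                shapes.append(x.shape)
                x = self.pool(x)
                shapes.append(x.shape)
                x = self.classifier(x.reshape(1, x.shape[1]))
                shapes.append(x.shape)
            nn.Module.train(self, was_training and not self._frozen)
        return shapes


def build_backbone(cfg: BackboneConfig | None = None, rng=None) -> MobileNetV2:
    return MobileNetV2(cfg, rng=rng)
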