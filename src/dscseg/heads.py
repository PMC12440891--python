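"""Segmentation heads: strip-pooling ASPP, attention-recalibrated cascade
feature fusion, decoder, and full-model assembly.

The encoder applies a six-branch spatial pyramid (S-ASPP) to the deepest
1/16 features: a 1×1 convolution, three 3×3 depthwise separable dilated
convolutions at increasing rates, global-average-pool image features, and a
strip-pooling branch whose channel-preserving gated map joins the
concatenation directly.  The concatenation is projected back to the pyramid
width and, optionally, recalibrated by CBAM.

The decoder fuses the 1/8 and 1/16 backbone taps through cascade feature
fusion with attention recalibration (C-CFF):

    F3 = BN(κ(F1)) + BN(φ(up₂(F2)))          κ: 1×1, φ: dilated 3×3 (separable)
    G  = M_c(F3) ⊙ F3
    Fc = ReLU( M_s(G) ⊙ G )

and concatenates [reduced 1/4 features | up₄(S-ASPP) | up₂(Fc)] before two
3×3 depthwise separable convolutions, a 1×1 classifier, and 4× bilinear
upsampling back to the input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .backbone import BackboneConfig, MobileNetV2
from .blocks import CBAM, ChannelAttention, ConvBNAct, DSDConv, SpatialAttention, StripPooling
from .nn import Tensor
from .nn import autograd as ag

__all__ = [
    "ModelConfig",
    "SASPP",
    "CCFF",
    "DSCDeepLabV3Plus",
    "assemble_model",
    "make_ablation_variant",
    "ABLATION_GROUPS",
]


@dataclass(frozen=True)
class ModelConfig:
    """Every architectural knob of the segmentation model.

    The widths below are the frozen defaults of this package: pyramid width
    256 with rates (6, 12, 18) at output stride 16, a 48-channel low-level
    reduction, a 256-channel cascade-fusion output, and two 288-channel
    separable 3×3 stages in the decoder.
    """

    num_classes: int = 3
    output_stride: int = 16
    aspp_rates: tuple[int, int, int] = (6, 12, 18)
    aspp_width: int = 256
    cff_width: int = 256
    lowlevel_width: int = 48
    decoder_width: int = 288
    decoder_convs: int = 2
    aspp_dropout: float = 0.1
    use_s_aspp: bool = True
    use_cbam_after_aspp: bool = True
    use_c_cff: bool = True
    cff_attention: str = "cbam"  # none | cam | sam | cbam
    attention_reduction: int = 16
    spatial_kernel: int = 7

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        r = self.aspp_rates
        if len(r) != 3 or not (r[0] < r[1] < r[2]):
            raise ValueError("aspp_rates must be three strictly increasing ints")
        if self.cff_attention not in ("none", "cam", "sam", "cbam"):
            raise ValueError(f"unknown cff_attention {self.cff_attention!r}")
        if self.decoder_convs not in (1, 2):
            raise ValueError("decoder_convs must be 1 or 2")


class SASPP(nn.Module):
    """Spatial pyramid over the deepest encoder features.

    Six parallel branches when ``use_s_aspp`` (1×1, three separable dilated
    3×3, image pooling, strip pooling); the plain five-branch pyramid
    otherwise.  Concatenation → 1×1 projection to ``aspp_width`` → dropout →
    optional CBAM.
    """

    def __init__(self, in_channels: int, cfg: ModelConfig, rng=None):
        super().__init__()
        w = cfg.aspp_width
        self.cfg = cfg
        self.branch1 = ConvBNAct(in_channels, w, 1, rng=rng)
        self.branch2 = DSDConv(in_channels, w, 3, dilation=cfg.aspp_rates[0], rng=rng)
        self.branch3 = DSDConv(in_channels, w, 3, dilation=cfg.aspp_rates[1], rng=rng)
        self.branch4 = DSDConv(in_channels, w, 3, dilation=cfg.aspp_rates[2], rng=rng)
        self.image_pool = nn.GlobalAvgPool2d()
        self.image_conv = ConvBNAct(in_channels, w, 1, rng=rng)
        concat_ch = 5 * w
        if cfg.use_s_aspp:
            self.strip = StripPooling(in_channels, rng=rng)
            concat_ch += in_channels
        self.project = ConvBNAct(concat_ch, w, 1, rng=rng)
        self.dropout = nn.Dropout(cfg.aspp_dropout, rng=np.random.default_rng(
            int(rng.integers(2**31)) if rng is not None else 0))
        if cfg.use_cbam_after_aspp:
            self.cbam = CBAM(w, cfg.attention_reduction, cfg.spatial_kernel, rng=rng)

    def forward(self, x):
        _, _, h, w = x.shape
        pooled = self.image_conv(self.image_pool(x))
        pooled = ag.upsample_bilinear(pooled, h, w)
        branches = [
            self.branch1(x),
            self.branch2(x),
            self.branch3(x),
            self.branch4(x),
            pooled,
        ]
        if self.cfg.use_s_aspp:
            branches.append(self.strip(x))
        out = self.dropout(self.project(ag.concat(branches, axis=1)))
        if self.cfg.use_cbam_after_aspp:
            out = self.cbam(out)
        return out


class CCFF(nn.Module):
    """Cascade feature fusion of a shallow map F1 and a 2×-smaller deep map F2,
    recalibrated by channel and/or spatial attention before the final ReLU."""

    def __init__(self, c1: int, c2: int, cfg: ModelConfig, rng=None):
        super().__init__()
        w = cfg.cff_width
        self.cfg = cfg
        self.reduce_f1 = nn.Conv2d(c1, w, 1, bias=False, rng=rng)
        self.bn_f1 = nn.BatchNorm2d(w)
        # dilated separable 3×3 on the upsampled deep map (no activation:
        # the fusion normalization and final ReLU follow)
        self.dilated_f2 = nn.Sequential(
            ConvBNAct(c2, c2, 3, dilation=2, groups=c2, activation=None, rng=rng),
            nn.Conv2d(c2, w, 1, bias=False, rng=rng),
        )
        self.bn_f2 = nn.BatchNorm2d(w)
        mode = cfg.cff_attention
        if mode in ("cam", "cbam"):
            self.cam = ChannelAttention(w, cfg.attention_reduction, rng=rng)
        if mode in ("sam", "cbam"):
            self.sam = SpatialAttention(cfg.spatial_kernel, rng=rng)

    def forward(self, f1: Tensor, f2: Tensor) -> Tensor:
        _, _, h1, w1 = f1.shape
        _, _, h2, w2 = f2.shape
        if (h1, w1) != (2 * h2, 2 * w2):
            raise ValueError(
                f"F1 spatial size {(h1, w1)} must be twice F2 {(h2, w2)}"
            )
        up = ag.upsample_bilinear(f2, h1, w1)
        f3 = ag.add(self.bn_f1(self.reduce_f1(f1)), self.bn_f2(self.dilated_f2(up)))
        g = f3
        mode = self.cfg.cff_attention
        if mode in ("cam", "cbam"):
            g = ag.mul(g, self.cam(g))
        if mode in ("sam", "cbam"):
            g = ag.mul(g, self.sam(g))
        return ag.relu(g)


class DSCDeepLabV3Plus(nn.Module):
    """Full encoder–decoder segmentation model."""

    def __init__(self, cfg: ModelConfig | None = None, rng=None):
        super().__init__()
        self.cfg = cfg or ModelConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.backbone = MobileNetV2(
            BackboneConfig(mode="segmentation", output_stride=self.cfg.output_stride),
            rng=rng,
        )
        self.aspp = SASPP(self.backbone.out_channels, self.cfg, rng=rng)
        if self.cfg.use_c_cff:
            self.cff = CCFF(32, 96, self.cfg, rng=rng)
        self.lowlevel = ConvBNAct(24, self.cfg.lowlevel_width, 1, rng=rng)
        concat_ch = self.cfg.lowlevel_width + self.cfg.aspp_width
        if self.cfg.use_c_cff:
            concat_ch += self.cfg.cff_width
        self.decoder = nn.Sequential()
        in_ch = concat_ch
        for _ in range(self.cfg.decoder_convs):
            self.decoder.append(DSDConv(in_ch, self.cfg.decoder_width, 3, rng=rng))
            in_ch = self.cfg.decoder_width
        self.classifier = nn.Conv2d(in_ch, self.cfg.num_classes, 1, bias=True, rng=rng)

    def set_backbone_frozen(self, frozen: bool) -> None:
        self.backbone.set_frozen(frozen)

    def forward(self, image: Tensor) -> Tensor:
        _, _, h, w = image.shape
        feats = self.backbone.forward_features(image)
        x = self.aspp(feats.os16_deep)
        _, _, h4, w4 = feats.os4.shape
        parts = [self.lowlevel(feats.os4), ag.upsample_bilinear(x, h4, w4)]
        if self.cfg.use_c_cff:
            fused = self.cff(feats.os8, feats.os16_mid)
            parts.append(ag.upsample_bilinear(fused, h4, w4))
        y = ag.concat(parts, axis=1)
        y = self.decoder(y)
        y = self.classifier(y)
        return ag.upsample_bilinear(y, h, w)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Class-index mask for an (N, 3, H, W) float array."""
        with nn.no_grad():
            logits = self(Tensor(image))
        return logits.data.argmax(axis=1)


ABLATION_GROUPS = ("group1", "group2", "group3", "group4")


def make_ablation_variant(which: str) -> ModelConfig:
    """Configuration of the standard ablation ladder.

    * ``group1`` — MobileNetV2 backbone with separable dilated convolutions,
      plain five-branch pyramid, plain additive fusion decoder (no cascade
      fusion, no attention).
    * ``group2`` — group1 + strip-pooling pyramid branch + CBAM after it.
    * ``group3`` — group1 + attention-recalibrated cascade feature fusion.
    * ``group4`` — the full model (the default configuration).
    """
    base = ModelConfig()
    variants = {
        "group1": replace(
            base, use_s_aspp=False, use_cbam_after_aspp=False, use_c_cff=False
        ),
        "group2": replace(base, use_c_cff=False),
        "group3": replace(base, use_s_aspp=False, use_cbam_after_aspp=False),
        "group4": base,
        "full": base,
    }
    if which not in variants:
        raise ValueError(f"unknown ablation variant {which!r}; pick from "
                         f"{ABLATION_GROUPS + ('full',)}")
    return variants[which]


def assemble_model(
    cfg: ModelConfig | None = None, seed: int | None = None
) -> DSCDeepLabV3Plus:
    rng = np.random.default_rng(seed if seed is not None else 0)
    return DSCDeepLabV3Plus(cfg, rng=rng)
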