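# Methods

## Model

`dscseg` implements an encoder–decoder semantic segmentation network for
three-class crop/weed mapping (background / corn / weed, plus an ignore
label 255 excluded from loss and metrics).

**Encoder.** A MobileNetV2 feature extractor (width multiplier 1.0) built
stage by stage from the standard bottleneck table: stem 3×3 stride 2 to 32
channels, then inverted residual stages (t, c, n, s) =
(1,16,1,1), (6,24,2,2), (6,32,3,2), (6,64,4,2), (6,96,3,1), (6,160,3,2),
(6,320,1,1). Each inverted residual expands by t with a 1×1 convolution
(ReLU6), filters with a depthwise 3×3 (ReLU6), and projects linearly back —
no nonlinearity after the projection — with a skip connection exactly when
stride = 1 and input/output channels match. In classification mode the
1280-channel 1×1 convolution, global average pool and linear classifier
complete the table (3.50M parameters at 1000 classes, matching the reference
implementation of this backbone). In segmentation mode those three are
dropped and, at output stride 16, the stride-2 entry of the 160-channel
stage becomes stride 1 while later depthwise kernels take dilation 2, so the
deepest features stay at 1/16 resolution. Taps: 1/4 (24 ch), 1/8 (32 ch),
1/16 (96 ch), 1/16 (320 ch).

**S-ASPP.** The 320-channel 1/16 features enter six parallel branches:
(1) 1×1 convolution; (2–4) 3×3 depthwise separable *dilated* convolutions at
rates 6/12/18; (5) global average pooling → 1×1 → bilinear broadcast;
(6) strip pooling. Branches 1–5 emit 256 channels. The strip-pooling branch
computes row means `y^h` (length H) and column means `y^v` (length W) per
channel, passes each through a depthwise 1-D convolution (kernel 3,
padding 1), broadcast-sums them into an H×W map, and gates the input:
`z = x ⊙ σ(f(y))` with f a depthwise 1×1 convolution. Its 320-channel gated
map joins the concatenation directly (the gate is channel-preserving by
construction; a dedicated channel-mixing reduction would roughly double the
module's cost for no structural gain). The concatenation (5·256 + 320
channels) is projected by a 1×1 convolution to 256, dropout 0.1 is applied,
and a CBAM block recalibrates the result.

**Attention.** Channel attention: `M_c(F) = σ(ω F^c_max + ω F^c_avg)` with a
shared two-layer perceptron ω (no biases, ReLU between layers, hidden width
`max(1, C/16)`; the ratio 16 is the usual default, and C must divide by it
when C ≥ 16). Spatial attention: channel-mean and channel-max maps are
concatenated (2×H×W) and convolved with a single 7×7 kernel, padding 3, then
σ. CBAM applies them sequentially: `out = M_s(G) ⊙ G`, `G = M_c(F) ⊙ F`.
The CBAM after the pyramid and the one inside the fusion module have
independent weights.

**C-CFF decoder fusion.** The 1/8 tap (F1) and the 1/16 tap (F2) are fused
as `F3 = BN(κ(F1)) + BN(φ(up₂(F2)))` where κ is a 1×1 convolution, up₂ is
bilinear, and φ is a depthwise separable 3×3 with dilation 2; both paths emit
256 channels. F3 is recalibrated (`G = M_c ⊙ F3`, `τ = M_s(G) ⊙ G`) and
rectified: `Fc = ReLU(τ)`. A switch selects none / channel-only /
spatial-only / full recalibration for ablations.

**Decoder.** `[1×1-reduced 1/4 features (48 ch) | up₄(S-ASPP) | up₂(Fc)]`
are concatenated and passed through two 3×3 depthwise separable convolutions
at 288 channels, a 1×1 classifier, and 4× bilinear upsampling to the input
resolution. A one-convolution decoder variant is available
(`decoder_convs=1`). All bilinear resampling uses half-pixel centers
(corner alignment disabled).

### Width choices

The published description of this architecture fixes the topology but not
every branch width. Defaults here follow DeepLabv3+ conventions where they
exist (pyramid width 256, rates 6/12/18 at output stride 16, 48-channel
low-level reduction) and were otherwise fixed once against the
architecture's published complexity budget (2.89M parameters,
15.3 GFLOPs at 512²), then frozen:

* fusion output width 256 — the published ablation deltas (+0.10M
  parameters, +1.1 GMACs when the fusion module is added) are only
  consistent with a ~256-channel fusion output, most of whose cost is the
  widened decoder concatenation;
* decoder width 288;
* strip-pooling 1-D and fusion convolutions depthwise — channel-mixing 1-D
  convolutions at 320 channels would add ~0.7M parameters, far outside the
  budget.

With these frozen defaults the profiler reports 2.957M / 15.02 GFLOPs for
the full model and 2.743M for the plain-pyramid ablation variant (published:
2.890M / 15.326 GFLOPs and 2.745M; all within ±2.5%).

## Complexity profiling

`profile(model, (H, W))` counts trainable parameters exactly and accumulates
multiply–accumulates during a real forward pass: convolutions contribute
`k_h·k_w·(C_in/groups)·C_out·H_out·W_out`, linear layers `C_in·C_out`, batch
normalizations one multiply–add per element. Elementwise activations,
pooling and bilinear resampling are not counted (the convention of standard
convnet profilers). Reported GFLOPs use FLOPs = 2·MACs; this convention was
calibrated once against the widely quoted complexity of the stock
MobileNetV2 DeepLabv3+ at 512² (≈56 GFLOPs, which a conv-MAC walk reproduces
only as 2×MACs), and both conventions are always printed. A parameterized
layer without a declared MAC rule raises rather than being silently skipped.

## Training

Per-pixel softmax cross-entropy over scored pixels (ignore label excluded
from both sum and divisor; all-ignored batches contribute zero loss with a
warning). SGD with momentum 0.9 and weight decay 1e-4. Defaults follow the
two-phase transfer-learning recipe: learning rate 0.007 decaying on a cosine
law to 1% of the maximum over 300 epochs (a polynomial option with the same
endpoints exists), the first 100 epochs with a frozen backbone at batch
size 8, the remainder unfrozen at batch size 4, validation and
checkpointing every 20 epochs (per-epoch validation available via
`eval_interval_epochs=1`). Freezing stops both gradient updates and
batch-norm statistics updates; unfreezing resumes from the current state.
Runs are fully seeded (weight init, shuffling, dropout) and reproducible on
one device.

mIoU averages TP/(TP+FP+FN) over classes, as a percentage, from an integer
confusion matrix (rows = truth). Classes absent from both prediction and
truth (empty union) are excluded from the mean by default;
`absent_class_iou=1.0` switches to the convention that scores them perfect.

## Synthetic scenes

The generator emulates nadir field photographs at the desk scale: a brown
soil base modulated by low-frequency illumination noise and fine grain; one
to three maize plants, each 5–9 elongated leaves (rotated ellipses, axis
ratio ≈ 0.2) radiating from a stem center — the directional geometry strip
pooling targets; 2–8 weed rosettes of 3–6 small leaves drawn on top; mild
shared shading and sensor noise. Labels are exact by construction. Leaf
widths are rescaled until the maize pixel share lands in a configured range
(default 10–40%, measured after weeds overdraw maize), and weed leaf axes
have an absolute floor (half-length 2.5 px, half-width 1.2 px) because a
rosette has a minimum physical size regardless of rendering resolution —
without it, 64×64 scenes contain sub-pixel weeds no model could resolve.
Scenes are bit-reproducible given (n, size, seed).

What the generator does **not** emulate: perspective and leaf occlusion
ordering, species-level weed morphology, specular highlights and shadows,
motion blur, inter-class color ambiguity beyond a small jitter, and the
label noise of human annotation. Tests passing on synthetic scenes therefore
demonstrate that the architecture, losses, metrics and training loop are
correct and that the model can fit plausibly structured data — not field
accuracy on real imagery.

The sixfold augmentation emits, per input: the original, horizontal flip,
rotation uniform in ±25° (image border reflected; mask resampled
nearest-neighbor, out-of-frame pixels set to the ignore label), Gaussian
blur σ ∈ [1, 2] (image only), random crop to 80% area resized back (mask
nearest-neighbor), and HSV jitter (hue ±10°, saturation/value ±20%; mask
untouched). Geometric operations apply the identical spatial map to image
and mask; no augmentation ever introduces a new class label. Train/val
splitting uses `floor(ratio·n + 0.5)` and a seeded permutation.

## Numerical choices

* float32 throughout; convolutions evaluated as kernel-tap loops over BLAS
  matmuls (peak memory stays proportional to activations).
* Batch normalization: eps 1e-5, momentum 0.1, unbiased running variance.
* The logistic gate is computed in its numerically stable form and clamped
  one representable float32 step away from 0 and 1, so attention and
  strip-pooling gates are strictly inside (0,1) even at saturating inputs.
* Kaiming-normal weight init (fan-in, gain √2); BN γ=1, β=0; zero biases.
* Tied maxima in max-pooling share the gradient equally, keeping backward
  passes deterministic.
* Bilinear resampling is expressed with dense per-axis interpolation
  matrices; its transpose is the exact backward operator.

## Desk-scale test sizes

The test suite exercises the published 512×512 geometry where the claim is
about geometry or complexity (stage-table fidelity, parameter/FLOP totals)
and otherwise uses 32–128 px scenes, which the pure-NumPy stack trains at
interactive speed. The learnability check overfits 8 synthetic 64×64 scenes
for 300 SGD steps (batch 4, lr 0.15, polynomial decay, unfrozen backbone —
with random initialization there are no pretrained features worth freezing)
and reaches ≈86% training mIoU; the residual error concentrates in weed
boundaries, as expected for 4×-upsampled logits at that resolution.

## Known limitations

* No GPU path and no mixed precision; wall-clock training at 512×512 is far
  slower than a framework implementation (the package targets correctness,
  architecture analysis and desk-scale experiments).
* No pretrained backbone weights are bundled; the checkpoint format is a
  plain name → array archive, and externally converted MobileNetV2 weights
  can be loaded by name mapping.
* FPS is reported informationally only; it is hardware-dependent and not a
  tested quantity.
* The exact decoder concatenation order and two under-specified widths are
  package choices (documented above); alternative choices shift parameter
  and FLOP totals by a few percent.
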