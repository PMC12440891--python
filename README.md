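# dscseg — lightweight maize/weed semantic segmentation

`dscseg` implements a lightweight encoder–decoder segmentation network for
distinguishing maize seedlings from weeds in field images, aimed at the kind
of per-pixel crop/weed mapping that precision spraying and robotic weeding
need on embedded hardware. Every pixel of an RGB field image is classified
into {background, corn, weed}.

The architecture is a DeepLabv3+-style encoder–decoder slimmed down by three
ideas:

* **MobileNetV2 backbone** with inverted residual bottlenecks
  (expand → depthwise 3×3 → linear 1×1 projection, skip connections at
  stride 1), run at output stride 16 via the dilation trick.
* **Depthwise separable dilated convolutions (DSDConv)** replace every dense
  3×3 in the spatial pyramid and decoder: a per-channel dilated k×k filter
  followed by a 1×1 channel mixer, cutting a 3×3 layer's multiply–accumulates
  per pixel from `9·C_in·C_out` to `9·C_in + C_in·C_out` (≈ 88.5% fewer at
  256 channels).
* **Directional context and attention.** The spatial pyramid (S-ASPP) has six
  branches — 1×1, three dilated DSDConv (rates 6/12/18), image pooling, and a
  *strip pooling* gate built from row/column averages

  `y^h_i = (1/W) Σ_j x_ij`, `y^v_j = (1/H) Σ_i x_ij`, `z = x ⊙ σ(f(y))`,

  which suits the elongated, radially arranged leaves of maize plants.
  A CBAM block (channel gate `M_c(F) = σ(ω F^c_max + ω F^c_avg)`, then a 7×7
  spatial gate) recalibrates the pyramid output. The decoder fuses the 1/8
  and 1/16 backbone taps by cascade feature fusion with CBAM recalibration
  (C-CFF): `F3 = BN(κ(F1)) + BN(φ(up₂(F2)))`, `Fc = ReLU(M_s(G) ⊙ G)` with
  `G = M_c(F3) ⊙ F3`.

Training uses per-pixel cross-entropy `L = −(1/N) Σ_i Σ_c y_ic log p_ic` and
accuracy is mean intersection-over-union,
`mIoU = (1/n) Σ_i TP_i/(TP_i+FP_i+FN_i) × 100%`.

The full model has **2.96M trainable parameters and 15.02 GFLOPs** at a
512×512 input (FLOPs = 2×MACs; the profiler prints both conventions), versus
tens of millions of parameters and >100 GFLOPs for classic dense
segmentation networks of comparable accuracy.

Everything — including the network layers, backprop, and SGD — runs on a
small NumPy autograd core (`dscseg.nn`), so the package has no deep-learning
framework dependency and is CPU-only by design. It is a reference and
desk-scale experimentation implementation, not a GPU training harness.

Because no public maize/weed dataset accompanies the architecture, the
package ships a seeded synthetic scene generator (soil texture, maize plants
drawn as radiating elongated leaves, small weed rosettes, exact labels) plus
the standard sixfold augmentation scheme (original + flip, rotation,
Gaussian blur, random crop, HSV jitter), so the entire pipeline is
exercisable end to end without external data.

## Worked example

Overfitting a handful of synthetic scenes is the quickest end-to-end sanity
check that the architecture, loss, and optimizer actually learn:

```python
from dscseg import generate_synthetic_field, assemble_model, TrainConfig, train, evaluate

scenes = generate_synthetic_field(n=8, size=64, seed=42)
model = assemble_model(seed=0)
cfg = TrainConfig(lr_max=0.15, lr_schedule="poly", epochs_total=150,
                  epochs_frozen=0, batch_unfrozen=4, eval_interval_epochs=50, seed=1)
history = train(model, scenes, scenes, cfg)

report = evaluate(model, scenes)
print(f"training-set mIoU after {cfg.epochs_total} epochs: {report['miou']:.2f}%")
print("per-class IoU (background, corn, weed):",
      [f"{100*v:.1f}%" for v in report["per_class_iou"]])
```

Output (≈2 minutes on one CPU core):

```
training-set mIoU after 150 epochs: 85.96%
per-class IoU (background, corn, weed): ['94.3%', '87.4%', '76.2%']
```

So after 300 SGD steps the network reproduces the 8 training scenes at ~86%
mIoU: background and maize are segmented nearly perfectly, while the small
weed rosettes — a few pixels wide at this resolution, and recovered through
4× upsampled logits — account for most of the residual error. That is the
expected difficulty ordering for this architecture.

The same workflows are available from the shell:

```bash
dscseg synth --n 100 --size 512 --seed 0 --out data/synth   # VOC-layout dataset
dscseg train --config config.yaml                           # two-phase SGD schedule
dscseg eval  --ckpt runs/run0/checkpoints/best.npz --data data/synth
dscseg predict --ckpt runs/run0/checkpoints/best.npz --image field.jpg --out mask.png
dscseg profile --variant full                               # params / MACs / GFLOPs
```

`dscseg profile` prints, for the full model and the ablation ladder
(`group1` = backbone + DSDConv only, `group2` = + strip-pooling pyramid and
CBAM, `group3` = + cascade fusion, `group4` = full):

```
full:   params 2.957M  7.512 GMACs  15.023 GFLOPs
group1: params 2.743M  6.036 GMACs  12.073 GFLOPs
```

The default training configuration follows the two-phase transfer-learning
recipe: SGD (momentum 0.9, weight decay 1e-4), initial learning rate 0.007
decaying to 1% of the maximum, 300 epochs — the first 100 with a frozen
backbone at batch size 8, the rest unfrozen at batch size 4 — validating
every 20 epochs at 512×512.

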