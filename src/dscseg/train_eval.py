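"""Loss, segmentation metrics, the training schedule, and complexity profiling.

The loss is per-pixel multi-class cross-entropy

    L = -(1/N) Σ_i Σ_c y_ic log p_ic

averaged over the N scored (non-ignore) pixels, with p the softmax of the
logits.  Accuracy is mean intersection-over-union,

    mIoU = (1/n) Σ_i TP_i / (TP_i + FP_i + FN_i) × 100%,

computed from a confusion matrix accumulated over all scored pixels.  Classes
absent from both prediction and truth (empty union) are excluded from the
mean by default; ``absent_class_iou=1.0`` restores the convention that counts
them as perfectly segmented.

Training follows the two-phase transfer-learning recipe: SGD with momentum
0.9, initial learning rate 0.007 decaying on a cosine law to 1% of the
maximum, weight decay 1e-4, 300 epochs of which the first 100 run with a
frozen backbone at batch size 8 and the remaining 200 with the backbone
unfrozen at batch size 4, validating every 20 epochs.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .data import SegSample, IGNORE_LABEL
from .heads import DSCDeepLabV3Plus
from .nn import Tensor, autograd as ag
from .nn.optim import SGD, cosine_lr, poly_lr
from .profiler import ProfileReport, profile

__all__ = [
    "TrainConfig",
    "ConfusionMatrix",
    "cross_entropy",
    "miou",
    "evaluate",
    "train",
    "profile",
    "ProfileReport",
]


@dataclass
class TrainConfig:
    lr_max: float = 0.007
    lr_min_fraction: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    epochs_total: int = 300
    epochs_frozen: int = 100
    batch_frozen: int = 8
    batch_unfrozen: int = 4
    eval_interval_epochs: int = 20
    lr_schedule: str = "cosine"  # cosine | poly
    seed: int = 0
    ignore_label: int = IGNORE_LABEL
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if not (0 <= self.epochs_frozen < self.epochs_total):
            raise ValueError("epochs_frozen must be in [0, epochs_total)")
        if min(self.batch_frozen, self.batch_unfrozen) < 1:
            raise ValueError("batch sizes must be >= 1")

    def lr_at(self, epoch: int) -> float:
        fn = cosine_lr if self.lr_schedule == "cosine" else poly_lr
        return fn(epoch, self.epochs_total, self.lr_max, self.lr_min_fraction)


def cross_entropy(logits, mask, ignore_label: int = IGNORE_LABEL):
    """Mean cross-entropy over scored pixels.

    ``logits``: (N, M, H, W) Tensor or array; ``mask``: (N, H, W) integer
    labels.  Pixels labeled ``ignore_label`` are excluded from both the sum
    and the divisor N.  If every pixel is ignored the loss is defined as
    zero and a warning is emitted.
    """
    if not isinstance(logits, Tensor):
        logits = Tensor(logits)
    loss, count = ag.softmax_cross_entropy(logits, np.asarray(mask), ignore_label)
    if count == 0:
        warnings.warn("all pixels carry the ignore label; loss defined as 0")
    return loss


class ConfusionMatrix:
    """n×n pixel-count matrix; rows index truth, columns prediction."""

    def __init__(self, num_classes: int, ignore_label: int = IGNORE_LABEL):
        if num_classes < 2:
            raise ValueError("need at least two classes")
        self.num_classes = num_classes
        self.ignore_label = ignore_label
        self.counts = np.zeros((num_classes, num_classes), dtype=np.int64)

    def update(self, pred_mask, true_mask) -> "ConfusionMatrix":
        pred = np.asarray(pred_mask).ravel()
        true = np.asarray(true_mask).ravel()
        if pred.shape != true.shape:
            raise ValueError("prediction and truth must share a shape")
        keep = true != self.ignore_label
        pred, true = pred[keep], true[keep]
        n = self.num_classes
        if pred.size and (
            pred.min() < 0 or pred.max() >= n or true.min() < 0 or true.max() >= n
        ):
            raise ValueError(f"label outside [0, {n})")
        self.counts += np.bincount(
            true * n + pred, minlength=n * n
        ).reshape(n, n)
        return self

    @property
    def per_class_iou(self) -> np.ndarray:
        """IoU_i = TP / (TP + FP + FN); NaN where the union is empty."""
        tp = np.diag(self.counts).astype(np.float64)
        fp = self.counts.sum(axis=0) - tp
        fn = self.counts.sum(axis=1) - tp
        union = tp + fp + fn
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(union > 0, tp / union, np.nan)


def miou(cm: ConfusionMatrix, absent_class_iou: float | None = None) -> float:
    """Mean IoU as a percentage.

    Classes with an empty union are skipped unless ``absent_class_iou`` gives
    the value to substitute (commonly 1.0).
    """
    iou = cm.per_class_iou
    if absent_class_iou is not None:
        iou = np.where(np.isnan(iou), absent_class_iou, iou)
    else:
        iou = iou[~np.isnan(iou)]
    if iou.size == 0:
        return 0.0
    return float(iou.mean() * 100.0)


def _to_batch(samples: list[SegSample]) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack(
        [s.image.astype(np.float32).transpose(2, 0, 1) / 255.0 for s in samples]
    )
    masks = np.stack([s.mask.astype(np.int64) for s in samples])
    return imgs, masks


def evaluate(
    model: DSCDeepLabV3Plus,
    samples: list[SegSample],
    batch_size: int = 4,
    ignore_label: int = IGNORE_LABEL,
) -> dict:
    """Confusion-matrix evaluation; returns mIoU, per-class IoU and mean loss."""
    cm = ConfusionMatrix(model.cfg.num_classes, ignore_label)
    was_training = model.training
    model.eval()
    losses = []
    with nn.no_grad():
        for i in range(0, len(samples), batch_size):
            imgs, masks = _to_batch(samples[i : i + batch_size])
            logits = model(Tensor(imgs))
            loss, count = ag.softmax_cross_entropy(logits, masks, ignore_label)
            if count:
                losses.append(loss.item())
            cm.update(logits.data.argmax(axis=1), masks)
    model.train(was_training)
    return {
        "miou": miou(cm),
        "per_class_iou": cm.per_class_iou.tolist(),
        "loss": float(np.mean(losses)) if losses else 0.0,
        "confusion": cm.counts.tolist(),
    }


def train(
    model: DSCDeepLabV3Plus,
    train_set: list[SegSample],
    val_set: list[SegSample] | None,
    cfg: TrainConfig,
    progress: bool = False,
    start_epoch: int = 0,
) -> dict:
    """Two-phase (frozen → unfrozen backbone) SGD training.

    Returns a history dict with per-epoch loss/learning rate and periodic
    validation mIoU; writes CSV history and checkpoints when
    ``cfg.checkpoint_dir`` is set.  Fully deterministic given ``cfg.seed``.
    ``start_epoch`` resumes a run: epoch numbering and the learning-rate
    schedule continue from that point.
    """
    if not train_set:
        raise ValueError("training set is empty")
    if val_set is not None and len(val_set) == 0:
        raise ValueError("validation set is empty (pass None to skip)")
    rng = np.random.default_rng(cfg.seed + start_epoch)
    opt = SGD(model.parameters(), lr=cfg.lr_at(0), momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    history = {"epoch": [], "phase": [], "lr": [], "train_loss": [],
               "val_loss": [], "val_miou": []}
    best = {"miou": -1.0, "epoch": -1}
    epochs = range(start_epoch, cfg.epochs_total)
    if progress:
        from tqdm import tqdm

        epochs = tqdm(epochs, desc="train")
    for epoch in epochs:
        frozen = epoch < cfg.epochs_frozen
        model.set_backbone_frozen(frozen)
        model.train()
        batch = cfg.batch_frozen if frozen else cfg.batch_unfrozen
        lr = cfg.lr_at(epoch)
        opt.lr = lr

        order = rng.permutation(len(train_set))
        losses = []
        for i in range(0, len(order), batch):
            idx = order[i : i + batch]
            imgs, masks = _to_batch([train_set[j] for j in idx])
            logits = model(Tensor(imgs))
            loss, count = ag.softmax_cross_entropy(logits, masks, cfg.ignore_label)
            if count == 0:
                continue
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())

        val_loss = val_miou = float("nan")
        if (epoch + 1) % cfg.eval_interval_epochs == 0 or epoch == cfg.epochs_total - 1:
            if val_set:
                report = evaluate(model, val_set, batch, cfg.ignore_label)
                val_loss, val_miou = report["loss"], report["miou"]
                if ckpt_dir:
                    model.save(ckpt_dir / f"epoch{epoch + 1:04d}.npz")
                    if val_miou > best["miou"]:
                        best = {"miou": val_miou, "epoch": epoch + 1}
                        model.save(ckpt_dir / "best.npz")
        history["epoch"].append(epoch)
        history["phase"].append("frozen" if frozen else "unfrozen")
        history["lr"].append(lr)
        history["train_loss"].append(float(np.mean(losses)) if losses else 0.0)
        history["val_loss"].append(val_loss)
        history["val_miou"].append(val_miou)

    model.set_backbone_frozen(False)
    if ckpt_dir:
        model.save(ckpt_dir / "last.npz")
        _write_history_csv(ckpt_dir / "history.csv", history)
    history["best"] = best
    return history


def _write_history_csv(path, history) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "phase", "lr", "train_loss", "val_loss", "val_miou"])
        for i in range(len(history["epoch"])):
            w.writerow(
                [
                    history["epoch"][i],
                    history["phase"][i],
                    f"{history['lr'][i]:.6g}",
                    f"{history['train_loss'][i]:.6f}",
                    f"{history['val_loss'][i]:.6f}",
                    f"{history['val_miou'][i]:.4f}",
                ]
            )
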