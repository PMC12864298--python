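"""SSL dataset assembly, training loop, full-scene prediction, and metrics.

Training optimizes the soft Jaccard loss with decoupled-weight-decay Adam
under a per-step one-cycle learning-rate schedule, stopping early after a
fixed number of epochs without validation-loss improvement and restoring the
best-validation checkpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dryshift import raster_prep
from dryshift.types import LabelRaster, SceneRaster
from dryshift.ynet_model.loss import TrainLossSpec, jaccard_loss, jaccard_loss_from_logits, softmax
from dryshift.ynet_model.optim import AdamW, OneCycleLR


@dataclass
class PatchSample:
    """One training sample: channel-first patches plus a per-pixel label map."""

    optical: np.ndarray  # (C_opt, 2s, 2s)
    sar: np.ndarray  # (C_sar, s, s)
    labels: np.ndarray  # (2s, 2s) integer classes
    source: str = "labeled"  # "labeled" | "pseudo"


@dataclass
class TrainConfig:
    max_epochs: int = 300
    batch_size: int = 10
    weight_decay: float = 5e-4
    peak_lr: float = 1.58e-4
    patience: int = 10
    loss: TrainLossSpec = field(default_factory=TrainLossSpec)
    seed: int = 0

    def __post_init__(self):
        if min(self.max_epochs, self.batch_size, self.patience) < 1:
            raise ValueError("epoch/batch/patience fields must be positive")
        if self.weight_decay < 0 or self.peak_lr <= 0:
            raise ValueError("weight_decay and peak_lr must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def assemble_ssl_dataset(
    labeled: list[PatchSample],
    pseudo_labeled: list[PatchSample],
    mode: str = "ratio",
    unlabeled_fraction: float | None = None,
    extra_count: int | None = None,
    seed: int = 0,
) -> list[PatchSample]:
    """Mix labeled and pseudo-labeled patches into one training set.

    ``ratio`` mode keeps the training-set size fixed at ``len(labeled)`` and
    replaces ``round(r * N)`` of it with pseudo-labeled patches; ``augment``
    mode keeps every labeled patch and adds ``extra_count`` pseudo-labeled
    ones (all of them when ``extra_count`` is None).  Pseudo-labels are
    consumed by the loss exactly like ground truth.
    """
    rng = np.random.default_rng(seed)
    if mode == "ratio":
        if unlabeled_fraction is None:
            raise ValueError("ratio mode needs unlabeled_fraction")
        if not 0.0 <= unlabeled_fraction <= 0.9:
            raise ValueError("unlabeled_fraction must lie in [0, 0.9]")
        n = len(labeled)
        n_pseudo = int(round(unlabeled_fraction * n))
        n_lab = n - n_pseudo
        if n_pseudo > len(pseudo_labeled):
            raise ValueError(
                f"need {n_pseudo} pseudo-labeled patches, have {len(pseudo_labeled)}"
            )
        lab_idx = rng.choice(len(labeled), size=n_lab, replace=False)
        ps_idx = rng.choice(len(pseudo_labeled), size=n_pseudo, replace=False)
        out = [labeled[i] for i in lab_idx] + [pseudo_labeled[i] for i in ps_idx]
    elif mode == "augment":
        k = len(pseudo_labeled) if extra_count is None else int(extra_count)
        if k > len(pseudo_labeled):
            raise ValueError(f"requested {k} pseudo patches, have {len(pseudo_labeled)}")
        ps_idx = rng.choice(len(pseudo_labeled), size=k, replace=False)
        out = list(labeled) + [pseudo_labeled[i] for i in ps_idx]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _batch(samples: list[PatchSample]):
    opt = np.stack([s.optical for s in samples])
    sar = np.stack([s.sar for s in samples])
    lab = np.stack([s.labels for s in samples])
    return opt, sar, lab


def _eval_loss_and_metrics(model, samples, spec: TrainLossSpec, batch_size: int):
    losses, n_correct, n_valid = [], 0, 0
    preds, truths = [], []
    for i in range(0, len(samples), batch_size):
        opt, sar, lab = _batch(samples[i : i + batch_size])
        probs = model.predict_proba(opt, sar)
        losses.append(jaccard_loss(probs, lab, spec))
        pred = probs.argmax(axis=1)
        valid = np.ones(lab.shape, dtype=bool)
        if spec.ignore_class is not None:
            valid = lab != spec.ignore_class
        n_correct += int((pred[valid] == lab[valid]).sum())
        n_valid += int(valid.sum())
        preds.append(pred[valid])
        truths.append(lab[valid])
    oa = n_correct / max(n_valid, 1)
    report = evaluate_map(
        np.concatenate([p.ravel() for p in preds]),
        np.concatenate([t.ravel() for t in truths]),
        ignore_class=None,  # already filtered
    )
    return float(np.mean(losses)), oa, report.miou


def train_model(model, train_set, val_set, config: TrainConfig):
    """Optimize the Jaccard loss with early stopping on validation loss.

    Returns ``(model, history)`` where history is a per-epoch DataFrame with
    train/val loss, overall accuracy, and mIoU.  The best-validation
    parameters are restored before returning.  A NaN loss aborts.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    params = model.params()
    opt = AdamW(
        params,
        lr=config.peak_lr,
        weight_decay=config.weight_decay,
        no_decay=model.bn_params(),
    )
    steps_per_epoch = int(np.ceil(len(train_set) / config.batch_size))
    sched = OneCycleLR(config.peak_lr, total_steps=config.max_epochs * steps_per_epoch)

    best_loss, best_state, best_epoch = np.inf, None, -1
    history = []
    stall = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_set))
        ep_losses = []
        for i in range(0, len(order), config.batch_size):
            batch = [train_set[j] for j in order[i : i + config.batch_size]]
            opt_in, sar_in, lab = _batch(batch)
            logits = model.forward(opt_in, sar_in, training=True)
            loss, dlogits = jaccard_loss_from_logits(logits, lab, config.loss)
            if not np.isfinite(loss):
                raise RuntimeError(f"divergent (non-finite) loss at epoch {epoch}")
            model.zero_grad()
            model.backward(dlogits)
            opt.step(lr=sched.step())
            ep_losses.append(loss)
        val_loss, val_oa, val_miou = _eval_loss_and_metrics(
            model, val_set, config.loss, config.batch_size
        )
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(ep_losses)),
                "val_loss": val_loss,
                "val_oa": val_oa,
                "val_miou": val_miou,
            }
        )
        if val_loss < best_loss - 1e-12:
            best_loss, best_epoch, stall = val_loss, epoch, 0
            best_state = model.state_dict()
        else:
            stall += 1
            if stall >= config.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    return model, hist


# ---------------------------------------------------------------------------
# Full-scene prediction
# ---------------------------------------------------------------------------

def predict_map(
    model,
    optical: SceneRaster,
    sar: SceneRaster,
    optical_stats: raster_prep.NormalizationStats | None = None,
    sar_stats: raster_prep.NormalizationStats | None = None,
    optical_patch: int = 64,
) -> tuple[LabelRaster, np.ndarray]:
    """Stitch per-patch predictions into a full-scene class map.

    The scene is tiled into non-overlapping windows (the scene must divide
    evenly into the patch grid so the stitched map has no gaps), each window
    is normalized with the frozen training stats and pushed through the
    model, and the argmax class map plus the stitched probability volume are
    returned at the fine resolution.
    """
    oh, ow = optical.grid.shape[:2]
    if oh < optical_patch or ow < optical_patch:
        raise ValueError("scene smaller than one patch")
    if oh % optical_patch or ow % optical_patch:
        raise ValueError(
            f"scene {oh}x{ow} does not tile evenly into {optical_patch}-px patches"
        )
    opt_grid = (
        raster_prep.apply_normalization(optical, optical_stats).grid
        if optical_stats is not None
        else optical.grid
    )
    sar_grid = (
        raster_prep.apply_normalization(sar, sar_stats).grid
        if sar_stats is not None
        else sar.grid
    )
    sp = optical_patch // 2
    n_classes = model.config.n_classes
    probs_full = np.zeros((oh, ow, n_classes))
    for r0 in range(0, oh, optical_patch):
        for c0 in range(0, ow, optical_patch):
            opt_p = opt_grid[r0 : r0 + optical_patch, c0 : c0 + optical_patch]
            sar_p = sar_grid[r0 // 2 : r0 // 2 + sp, c0 // 2 : c0 // 2 + sp]
            probs = model.predict_proba(
                opt_p.transpose(2, 0, 1)[None], sar_p.transpose(2, 0, 1)[None]
            )[0]
            probs_full[r0 : r0 + optical_patch, c0 : c0 + optical_patch] = probs.transpose(
                1, 2, 0
            )
    classes = probs_full.argmax(axis=2).astype(np.uint8)
    label_raster = LabelRaster(
        labels=classes,
        pixel_size_m=optical.pixel_size_m,
        geotransform=optical.geotransform,
        crs=optical.crs,
    )
    return label_raster, probs_full


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Overall accuracy, IoU/F1 per class, and a row-normalized confusion matrix."""

    oa: float
    miou: float
    iou: dict
    f1: dict
    confusion_pct: np.ndarray  # rows = truth classes, normalized to 100 %
    counts: np.ndarray
    classes: list[int]

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.oa,
            "miou": self.miou,
            "iou": {int(k): v for k, v in self.iou.items()},
            "f1": {int(k): v for k, v in self.f1.items()},
            "classes": [int(c) for c in self.classes],
            "confusion_pct": self.confusion_pct.tolist(),
        }

    def render_table(self) -> str:
        lines = ["class  IoU     F1"]
        for c in self.classes:
            lines.append(f"{c:>5}  {self.iou[c]:.3f}  {self.f1[c]:.3f}")
        lines.append(f"Overall Accuracy: {self.oa:.3f}  mIoU: {self.miou:.3f}")
        return "\n".join(lines)


def f1_from_iou(iou: float) -> float:
    """Dice/Jaccard identity: F1 = 2*IoU / (1 + IoU)."""
    return 2.0 * iou / (1.0 + iou)


def evaluate_map(
    predicted: np.ndarray | LabelRaster,
    truth: np.ndarray | LabelRaster,
    ignore_class: int | None = 0,
) -> MetricsReport:
    """Pixel metrics between aligned class maps.

    OA = correct / valid pixels; per-class IoU = TP / (TP + FP + FN); mIoU is
    the unweighted mean over evaluated classes; F1 = 2TP / (2TP + FP + FN).
    Classes absent from both maps are excluded from the mean with a warning.
    Pixels whose truth equals ``ignore_class`` are dropped.
    """
    pred = predicted.labels if isinstance(predicted, LabelRaster) else np.asarray(predicted)
    tru = truth.labels if isinstance(truth, LabelRaster) else np.asarray(truth)
    if pred.shape != tru.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {tru.shape}")
    valid = np.ones(tru.shape, dtype=bool)
    if ignore_class is not None:
        valid &= tru != ignore_class  # predicted ignore at a valid pixel counts as error
    if not valid.any():
        raise ValueError("no valid pixels to evaluate")
    p, t = pred[valid].ravel(), tru[valid].ravel()
    n_classes = int(max(p.max(), t.max())) + 1
    counts = np.bincount(t * n_classes + p, minlength=n_classes * n_classes).reshape(
        n_classes, n_classes
    )
    classes = [
        c
        for c in range(n_classes)
        if c != ignore_class and (counts[c].sum() > 0 or counts[:, c].sum() > 0)
    ]
    skipped = [
        c
        for c in range(n_classes)
        if c != ignore_class and counts[c].sum() == 0 and counts[:, c].sum() == 0
    ]
    if skipped:
        warnings.warn(
            f"classes {skipped} absent from both maps; excluded from mIoU", stacklevel=2
        )
    iou, f1 = {}, {}
    for c in classes:
        tp = counts[c, c]
        fp = counts[:, c].sum() - tp
        fn = counts[c].sum() - tp
        iou[c] = float(tp / (tp + fp + fn)) if tp + fp + fn else float("nan")
        f1[c] = float(2 * tp / (2 * tp + fp + fn)) if tp + fp + fn else float("nan")
    oa = float(np.trace(counts) / counts.sum())
    miou = float(np.mean([iou[c] for c in classes]))
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion_pct = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
    return MetricsReport(
        oa=oa,
        miou=miou,
        iou=iou,
        f1=f1,
        confusion_pct=confusion_pct,
        counts=counts,
        classes=classes,
    )
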