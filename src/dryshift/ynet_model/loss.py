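"""Softmax activation and the soft Jaccard training loss."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TrainLossSpec:
    """Loss configuration: smoothing epsilon and an optional ignored class.

    The ignored class (default 0, the background/other class) is excluded both
    as a class term and as pixels: samples labeled with it contribute nothing
    to the loss or its gradient.
    """

    epsilon: float = 1e-6
    ignore_class: int | None = 0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax; probabilities sum to 1 along ``axis``."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _prepare(probs: np.ndarray, labels: np.ndarray, spec: TrainLossSpec):
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.ndim == 3 and labels.ndim == 2:  # single sample (C, H, W) + (H, W)
        probs = probs[None]
        labels = labels[None]
    elif not (probs.ndim == 4 and labels.ndim == 3):
        raise ValueError(
            f"expected probs (N, C, H, W) with labels (N, H, W); got {probs.shape} and {labels.shape}"
        )
    if probs.shape[0] != labels.shape[0] or probs.shape[2:] != labels.shape[1:]:
        raise ValueError(f"probs {probs.shape} and labels {labels.shape} are misaligned")
    n_classes = probs.shape[1]
    valid = np.ones(labels.shape, dtype=bool)
    if spec.ignore_class is not None:
        valid = labels != spec.ignore_class
    in_range = (labels >= 0) & (labels < n_classes)
    if np.any(valid & ~in_range):
        bad = labels[valid & ~in_range].ravel()[0]
        raise ValueError(f"label {int(bad)} outside [0, {n_classes})")
    classes = [c for c in range(n_classes) if c != spec.ignore_class]
    return probs, labels, valid, classes


def jaccard_loss(
    probs: np.ndarray, labels: np.ndarray, spec: TrainLossSpec | None = None
) -> float:
    """Soft Jaccard loss in [0, 1].

    ``1 - mean_c (sum p_c*y_c + eps) / (sum (p_c + y_c - p_c*y_c) + eps)``
    with sums over non-ignored pixels and the mean over non-ignored classes.
    """
    spec = spec or TrainLossSpec()
    probs, labels, valid, classes = _prepare(probs, labels, spec)
    eps = spec.epsilon
    ious = []
    for c in classes:
        p = probs[:, c][valid]
        y = (labels[valid] == c).astype(float)
        inter = float((p * y).sum())
        union = float((p + y - p * y).sum())
        ious.append((inter + eps) / (union + eps))
    return float(1.0 - np.mean(ious))


def jaccard_loss_grad(
    probs: np.ndarray, labels: np.ndarray, spec: TrainLossSpec | None = None
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the probabilities."""
    spec = spec or TrainLossSpec()
    squeeze = np.asarray(probs).ndim == 3
    probs, labels, valid, classes = _prepare(probs, labels, spec)
    eps = spec.epsilon
    grad = np.zeros_like(probs)
    ious = []
    k = len(classes)
    for c in classes:
        p = probs[:, c]
        y = (labels == c).astype(float)
        pv, yv = p[valid], y[valid]
        inter = float((pv * yv).sum()) + eps
        union = float((pv + yv - pv * yv).sum()) + eps
        ious.append(inter / union)
        # d(inter/union)/dp = (y*union - (1-y)*inter) / union^2 on valid pixels
        gc = np.where(valid, (y * union - (1.0 - y) * inter) / union**2, 0.0)
        grad[:, c] = -gc / k
    loss = float(1.0 - np.mean(ious))
    if squeeze:
        grad = grad[0]
    return loss, grad


def jaccard_loss_from_logits(
    logits: np.ndarray, labels: np.ndarray, spec: TrainLossSpec | None = None
) -> tuple[float, np.ndarray]:
    """Loss and gradient with respect to the logits (softmax folded in)."""
    probs = softmax(logits, axis=1 if logits.ndim == 4 else 0)
    loss, dprobs = jaccard_loss_grad(probs, labels, spec)
    axis = 1 if logits.ndim == 4 else 0
    inner = (dprobs * probs).sum(axis=axis, keepdims=True)
    dlogits = probs * (dprobs - inner)
    return loss, dlogits
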