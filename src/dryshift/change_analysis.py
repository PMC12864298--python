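"""Ensemble post-classification change detection and area accounting.

Per model, two dates' class maps are differenced pixel-wise into transition
codes and target-class loss/gain masks; a k-of-n majority vote over the model
masks yields the final change mask.  Areas are booked in hectares with signed
percent changes (half-even rounding to one decimal) and error margins equal
to area x misclassification rate, truncated toward zero to whole hectares.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dryshift.types import LabelRaster

DEFAULT_N_MODELS = 5
DEFAULT_VOTE_THRESHOLD = 3


def _as_labels(m) -> np.ndarray:
    return m.labels if isinstance(m, LabelRaster) else np.asarray(m)


def diff_maps(
    map_t1, map_t2, target_class: int, n_classes: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel-wise difference of two aligned class maps.

    Returns ``(transition, loss_mask, gain_mask)`` where the transition code
    is ``from_class * C + to_class``, the loss mask marks pixels leaving the
    target class, and the gain mask pixels entering it.
    """
    t1, t2 = _as_labels(map_t1), _as_labels(map_t2)
    if t1.shape != t2.shape:
        raise ValueError(f"misaligned maps: {t1.shape} vs {t2.shape}")
    c = n_classes if n_classes is not None else int(max(t1.max(), t2.max())) + 1
    transition = t1.astype(np.int64) * c + t2.astype(np.int64)
    loss = (t1 == target_class) & (t2 != target_class)
    gain = (t1 != target_class) & (t2 == target_class)
    return transition, loss, gain


def ensemble_change_vote(masks: list[np.ndarray], threshold: int = DEFAULT_VOTE_THRESHOLD):
    """Pixel set iff at least ``threshold`` of the model masks flag it.

    ``threshold = 1`` is the union, ``threshold = len(masks)`` the
    intersection; the default is 3-of-5.  Returns ``(majority_mask, votes)``.
    """
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    if not 1 <= threshold <= len(masks):
        raise ValueError(f"threshold must lie in [1, {len(masks)}]")
    shape = np.asarray(masks[0]).shape
    for m in masks[1:]:
        if np.asarray(m).shape != shape:
            raise ValueError("mixed mask shapes")
    votes = np.sum([np.asarray(m, dtype=np.int64) for m in masks], axis=0)
    return votes >= threshold, votes


def class_areas(
    label_map, pixel_size_m: float, n_classes: int | None = None
) -> dict[int, float]:
    """Hectares per class: count x pixel_size^2 / 10,000."""
    if pixel_size_m <= 0:
        raise ValueError("pixel_size_m must be positive")
    lab = _as_labels(label_map)
    c = n_classes if n_classes is not None else int(lab.max()) + 1
    counts = np.bincount(lab.ravel(), minlength=c)
    ha_per_px = pixel_size_m**2 / 1e4
    return {cls: float(counts[cls] * ha_per_px) for cls in range(c)}


def percent_change(area_t1: float, area_t2: float) -> float:
    """Signed percent change relative to t1, half-even rounded to 1 decimal."""
    if area_t1 <= 0:
        raise ValueError("percent change undefined for area_t1 <= 0")
    raw = 100.0 * (area_t2 - area_t1) / area_t1
    q = decimal.Decimal(repr(raw)).quantize(
        decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_EVEN
    )
    return float(q)


def error_margin(area_ha: float, misclassification_rate: float) -> int:
    """Integer-hectare margin: area x rate truncated toward zero.

    The rate is 1 minus the target class's diagonal of the row-normalized
    confusion matrix.
    """
    if not 0.0 <= misclassification_rate <= 1.0:
        raise ValueError("misclassification_rate must lie in [0, 1]")
    if area_ha < 0:
        raise ValueError("area must be non-negative")
    return math.trunc(area_ha * misclassification_rate)


@dataclass
class ChangeResult:
    """Per epoch-pair ensemble change products and the area ledger."""

    transitions: list  # [pair][model] transition rasters
    votes: list  # [pair] vote count rasters (0..n_models)
    majority_masks: list  # [pair] boolean loss masks
    areas_ha: list  # [epoch] target-class area in hectares (consensus map)
    percent_changes: list  # [pair] signed %
    error_margins: list  # [pair] integer hectares
    ledger: pd.DataFrame = None


def _consensus_map(maps: list[np.ndarray]) -> np.ndarray:
    """Per-pixel modal class across models (lowest class id on ties)."""
    stack = np.stack([_as_labels(m) for m in maps])
    n_classes = int(stack.max()) + 1
    counts = np.stack([(stack == c).sum(axis=0) for c in range(n_classes)])
    return counts.argmax(axis=0)


def change_summary(
    model_maps: list[list],
    target_class: int,
    pixel_size_m: float,
    misclassification_rate: float,
    years: list | None = None,
    vote_threshold: int = DEFAULT_VOTE_THRESHOLD,
) -> ChangeResult:
    """Compose diff -> vote -> areas -> percent change -> margin per epoch pair.

    ``model_maps[m][e]`` is model ``m``'s class map for epoch ``e``.  The
    per-epoch target-class area is measured on the per-pixel modal consensus
    map over models; the change masks come from the k-of-n vote over the
    per-model loss masks.
    """
    n_models = len(model_maps)
    if n_models < 1:
        raise ValueError("need at least one model")
    n_epochs = len(model_maps[0])
    if n_epochs < 2:
        raise ValueError("need at least two epochs")
    for maps in model_maps:
        if len(maps) != n_epochs:
            raise ValueError("all models must cover the same epochs")
    years = years if years is not None else list(range(n_epochs))
    threshold = min(vote_threshold, n_models)

    consensus = [
        _consensus_map([model_maps[m][e] for m in range(n_models)]) for e in range(n_epochs)
    ]
    areas = [
        class_areas(cm, pixel_size_m, n_classes=max(int(cm.max()) + 1, target_class + 1))[
            target_class
        ]
        for cm in consensus
    ]

    transitions, votes_list, masks, pcts, margins = [], [], [], [], []
    for e in range(n_epochs - 1):
        pair_transitions, pair_loss = [], []
        for m in range(n_models):
            tr, loss, _ = diff_maps(model_maps[m][e], model_maps[m][e + 1], target_class)
            pair_transitions.append(tr)
            pair_loss.append(loss)
        majority, votes = ensemble_change_vote(pair_loss, threshold=threshold)
        transitions.append(pair_transitions)
        votes_list.append(votes)
        masks.append(majority)
        pcts.append(percent_change(areas[e], areas[e + 1]))
        margins.append(error_margin(areas[e + 1], misclassification_rate))

    rows = [
        {
            "year": years[0],
            "area_ha": areas[0],
            "pct_change": None,
            "error_margin_ha": None,
        }
    ]
    for e in range(1, n_epochs):
        rows.append(
            {
                "year": years[e],
                "area_ha": areas[e],
                "pct_change": pcts[e - 1],
                "error_margin_ha": margins[e - 1],
            }
        )
    return ChangeResult(
        transitions=transitions,
        votes=votes_list,
        majority_masks=masks,
        areas_ha=areas,
        percent_changes=pcts,
        error_margins=margins,
        ledger=pd.DataFrame(rows),
    )
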