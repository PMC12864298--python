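"""Deterministic raster plumbing: composites, indices, normalization,
chunking, resampling, and tile-grouped split assignment.

Conventions: 0-based row/col coordinates, half-open windows, top-left origin,
pixel-is-area.  The optical grid is exactly twice the SAR grid resolution, so
each SAR window is half the optical window in both axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from dryshift.types import SceneRaster

logger = logging.getLogger(__name__)

OPTICAL_PATCH = 576
SAR_PATCH = 288

SPLITS = ("train", "val", "test")
TEST_FRACTION = 0.30
TRAIN_FRACTION_OF_POOL = 0.85


# ---------------------------------------------------------------------------
# Compositing and indices
# ---------------------------------------------------------------------------

def temporal_median_composite(
    stack: list[SceneRaster],
    validity_masks: list[np.ndarray] | None = None,
    nodata: float = -9999.0,
) -> SceneRaster:
    """Per-pixel, per-band median over the valid observations of a stack.

    ``validity_masks`` are boolean (rows, cols) arrays, True where the
    acquisition is usable (e.g. cloud-free).  Pixels with zero valid
    observations are set to ``nodata``.  Even-count medians are the mean of
    the two middle values.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    ref = stack[0]
    for r in stack[1:]:
        if r.grid.shape != ref.grid.shape:
            raise ValueError(f"shape mismatch: {r.grid.shape} vs {ref.grid.shape}")
        if r.band_names != ref.band_names:
            raise ValueError("band mismatch across stack")
        if r.geotransform != ref.geotransform:
            raise ValueError("geotransform mismatch across stack")
    data = np.stack([r.grid.astype(float) for r in stack])  # (t, rows, cols, bands)
    invalid = np.zeros(data.shape, dtype=bool)
    for t, r in enumerate(stack):
        if r.nodata is not None:
            invalid[t] |= r.grid == r.nodata
    if validity_masks is not None:
        if len(validity_masks) != len(stack):
            raise ValueError("one validity mask per raster required")
        for t, m in enumerate(validity_masks):
            if m.shape != data.shape[1:3]:
                raise ValueError("validity mask shape mismatch")
            invalid[t] |= ~np.asarray(m, dtype=bool)[:, :, None]
    data[invalid] = np.nan
    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="All-NaN slice")
        med = np.nanmedian(data, axis=0)
    med = np.where(np.isnan(med), nodata, med)
    return replace(ref, grid=med, nodata=nodata)


def compute_indices(optical: SceneRaster) -> SceneRaster:
    """Append NDVI and GNDVI bands to a raster holding Red, Green and NIR.

    NDVI = (NIR - Red) / (NIR + Red); GNDVI = (NIR - Green) / (NIR + Green).
    Zero-denominator pixels map to 0; outputs are confined to [-1, 1].
    """
    for name in ("Red", "Green", "NIR"):
        if name not in optical.band_names:
            raise ValueError(f"missing required band {name!r}")
    nir = optical.band("NIR").astype(float)
    red = optical.band("Red").astype(float)
    green = optical.band("Green").astype(float)

    def _nd(a, b):
        den = a + b
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den == 0, 0.0, (a - b) / np.where(den == 0, 1.0, den))
        return np.clip(out, -1.0, 1.0)

    grid = np.concatenate(
        [optical.grid, _nd(nir, red)[:, :, None], _nd(nir, green)[:, :, None]], axis=2
    )
    return optical.with_grid(grid, band_names=optical.band_names + ["NDVI", "GNDVI"])


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationStats:
    """Per-band min/max computed over the training split only."""

    minimum: np.ndarray
    maximum: np.ndarray
    band_names: list[str] | None = None

    def __post_init__(self):
        self.minimum = np.atleast_1d(np.asarray(self.minimum, dtype=float))
        self.maximum = np.atleast_1d(np.asarray(self.maximum, dtype=float))
        if self.minimum.shape != self.maximum.shape:
            raise ValueError("min/max shape mismatch")
        if np.any(self.maximum < self.minimum):
            raise ValueError("max < min for some band")

    @property
    def n_bands(self) -> int:
        return self.minimum.shape[0]


def fit_normalization(
    train_patches: list[np.ndarray | SceneRaster],
    band_names: list[str] | None = None,
) -> NormalizationStats:
    """Global per-band min/max over every pixel of the training patches.

    Accepts ``(rows, cols, bands)`` arrays or :class:`SceneRaster` objects;
    nodata samples are excluded.  The stats must never see validation or test
    content — that is the caller's contract.
    """
    if len(train_patches) == 0:
        raise ValueError("need at least one training patch")
    mins, maxs = None, None
    for p in train_patches:
        if isinstance(p, SceneRaster):
            arr, valid = p.grid, p.valid_mask()
            if band_names is None:
                band_names = list(p.band_names)
        else:
            arr = np.asarray(p, dtype=float)
            valid = np.isfinite(arr)
        masked = np.where(valid, arr, np.nan)
        import warnings as _warnings

        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.filterwarnings("ignore", message="All-NaN")
            pmin = np.nanmin(masked, axis=(0, 1))
            pmax = np.nanmax(masked, axis=(0, 1))
        mins = pmin if mins is None else np.fmin(mins, pmin)
        maxs = pmax if maxs is None else np.fmax(maxs, pmax)
    if np.any(np.isnan(mins)) or np.any(np.isnan(maxs)):
        raise ValueError("a band contains no valid data in any training patch")
    return NormalizationStats(minimum=mins, maximum=maxs, band_names=band_names)


def apply_normalization(
    raster: SceneRaster | np.ndarray, stats: NormalizationStats
) -> SceneRaster | np.ndarray:
    """Scale to [0, 1] with the frozen training-set stats, clipping overshoot.

    Bands with ``max == min`` map to 0 everywhere.
    """
    arr = raster.grid if isinstance(raster, SceneRaster) else np.asarray(raster, dtype=float)
    if arr.shape[-1] != stats.n_bands:
        raise ValueError(f"raster has {arr.shape[-1]} bands, stats describe {stats.n_bands}")
    span = stats.maximum - stats.minimum
    safe = np.where(span == 0, 1.0, span)
    out = np.clip((arr - stats.minimum) / safe, 0.0, 1.0)
    out = np.where(span == 0, 0.0, out)
    if isinstance(raster, SceneRaster):
        return raster.with_grid(out)
    return out


# ---------------------------------------------------------------------------
# Chunking and splits
# ---------------------------------------------------------------------------

@dataclass
class PatchRecord:
    patch_id: int
    grid_row: int  # patch index within the patch grid
    grid_col: int
    optical_window: tuple  # (row0, col0, height, width) on the fine grid
    sar_window: tuple  # (row0, col0, height, width) on the coarse grid
    tile_id: int | None = None
    split: str | None = None


@dataclass
class PatchSet:
    """Co-indexed optical/SAR/label patch windows with split assignment."""

    records: list[PatchRecord]
    optical_patch: int = OPTICAL_PATCH
    sar_patch: int = SAR_PATCH
    grid_shape: tuple = None  # (patch rows, patch cols)

    def __len__(self) -> int:
        return len(self.records)

    def by_split(self, split: str) -> list[PatchRecord]:
        return [r for r in self.records if r.split == split]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "patch_id": r.patch_id,
                    "tile_id": r.tile_id,
                    "grid_row": r.grid_row,
                    "grid_col": r.grid_col,
                    "opt_row0": r.optical_window[0],
                    "opt_col0": r.optical_window[1],
                    "opt_size": r.optical_window[2],
                    "sar_row0": r.sar_window[0],
                    "sar_col0": r.sar_window[1],
                    "sar_size": r.sar_window[2],
                    "split": r.split,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def chunk_scene(
    optical: SceneRaster,
    sar: SceneRaster,
    labels=None,
    optical_patch: int = OPTICAL_PATCH,
) -> PatchSet:
    """Divide a paired scene into co-indexed fine/coarse windows.

    The optical raster must be exactly twice the SAR resolution and cover the
    same extent; SAR windows are ``optical_patch // 2`` pixels.  Incomplete
    edge windows are dropped (logged), keeping a constant ground footprint.
    """
    if optical_patch % 2:
        raise ValueError("optical_patch must be even")
    oh, ow = optical.grid.shape[:2]
    sh, sw = sar.grid.shape[:2]
    if (oh, ow) != (2 * sh, 2 * sw):
        raise ValueError(
            f"optical {oh}x{ow} is not exactly 2x the SAR grid {sh}x{sw}"
        )
    if abs(optical.geotransform[0] - sar.geotransform[0]) > 1e-6 or abs(
        optical.geotransform[3] - sar.geotransform[3]
    ) > 1e-6:
        raise ValueError("optical and SAR extents are misaligned")
    sar_patch = optical_patch // 2
    n_rows = oh // optical_patch
    n_cols = ow // optical_patch
    if n_rows == 0 or n_cols == 0:
        raise ValueError("scene smaller than a single patch")
    dropped = (oh - n_rows * optical_patch) * ow + (ow - n_cols * optical_patch) * n_rows * optical_patch
    if dropped:
        logger.info("chunk_scene: dropped %d edge pixels outside the patch grid", dropped)
    records = []
    pid = 0
    for pr in range(n_rows):
        for pc in range(n_cols):
            records.append(
                PatchRecord(
                    patch_id=pid,
                    grid_row=pr,
                    grid_col=pc,
                    optical_window=(pr * optical_patch, pc * optical_patch, optical_patch, optical_patch),
                    sar_window=(pr * sar_patch, pc * sar_patch, sar_patch, sar_patch),
                )
            )
            pid += 1
    return PatchSet(
        records=records,
        optical_patch=optical_patch,
        sar_patch=sar_patch,
        grid_shape=(n_rows, n_cols),
    )


def _largest_remainder(total: int, fractions: list[float]) -> list[int]:
    """Apportion ``total`` items to categories by largest-remainder rounding."""
    raw = [f * total for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    short = total - sum(counts)
    remainders = np.array(raw) - np.array(counts)
    for idx in np.argsort(-remainders, kind="stable")[:short]:
        counts[idx] += 1
    return counts


def split_patches(
    patchset: PatchSet, tile_size_patches: int = 2, seed: int = 0
) -> PatchSet:
    """Assign whole tiles of patches to train/val/test.

    Patches are grouped into ``tile_size_patches`` x ``tile_size_patches``
    blocks of the patch grid; 30% of tiles (largest-remainder rounding) are
    held out as test, and the remaining pool is split 85/15 into train and
    validation.  Deterministic under ``seed``; no tile ever spans splits.
    Overall patch shares converge to 59.5 / 10.5 / 30 %.
    """
    if tile_size_patches < 1:
        raise ValueError("tile_size_patches must be >= 1")
    records = [replace(r) for r in patchset.records]
    for r in records:
        r.tile_id = (r.grid_row // tile_size_patches) * 10**6 + (
            r.grid_col // tile_size_patches
        )
    tiles = sorted({r.tile_id for r in records})
    if len(tiles) < 3:
        raise ValueError(f"need at least 3 tiles to split, got {len(tiles)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tiles))
    shuffled = [tiles[i] for i in order]

    n_test, n_pool = _largest_remainder(len(tiles), [TEST_FRACTION, 1 - TEST_FRACTION])
    n_train, n_val = _largest_remainder(
        n_pool, [TRAIN_FRACTION_OF_POOL, 1 - TRAIN_FRACTION_OF_POOL]
    )
    assignment = {}
    for t in shuffled[:n_test]:
        assignment[t] = "test"
    for t in shuffled[n_test : n_test + n_train]:
        assignment[t] = "train"
    for t in shuffled[n_test + n_train :]:
        assignment[t] = "val"
    for r in records:
        r.split = assignment[r.tile_id]
    return replace(patchset, records=records)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

RESAMPLE_MODES = ("maxpool_down", "meanpool_down", "bilinear_up")


def resample(raster: SceneRaster | np.ndarray, factor: int, mode: str):
    """Integer-factor resampling on the pixel-is-area grid.

    ``maxpool_down`` / ``meanpool_down`` take the blockwise max / mean and
    require dimensions divisible by ``factor``; ``bilinear_up`` interpolates
    with pixel-centre alignment, so constants stay constant in every mode.
    """
    if mode not in RESAMPLE_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {RESAMPLE_MODES}")
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    is_raster = isinstance(raster, SceneRaster)
    arr = raster.grid if is_raster else np.asarray(raster, dtype=float)
    squeeze = False
    if arr.ndim == 2:
        arr = arr[:, :, None]
        squeeze = True
    h, w, b = arr.shape
    if factor == 1:
        out = arr.copy()
        scale = 1.0
    elif mode in ("maxpool_down", "meanpool_down"):
        if h % factor or w % factor:
            raise ValueError(
                f"dimensions {h}x{w} not divisible by pooling factor {factor}"
            )
        blocks = arr.reshape(h // factor, factor, w // factor, factor, b)
        out = blocks.max(axis=(1, 3)) if mode == "maxpool_down" else blocks.mean(axis=(1, 3))
        scale = float(factor)
    else:  # bilinear_up
        hh, ww = h * factor, w * factor
        # Pixel-centre alignment: output centre (i + 0.5)/f - 0.5 in input coords.
        rr = (np.arange(hh) + 0.5) / factor - 0.5
        cc = (np.arange(ww) + 0.5) / factor - 0.5
        grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
        coords = np.stack([grid_r.ravel(), grid_c.ravel()])
        out = np.empty((hh, ww, b))
        for k in range(b):
            out[:, :, k] = ndimage.map_coordinates(
                arr[:, :, k], coords, order=1, mode="nearest"
            ).reshape(hh, ww)
        scale = 1.0 / factor
    if squeeze:
        out = out[:, :, 0]
    if not is_raster:
        return out
    gt = raster.geotransform
    new_gt = (gt[0], gt[1] * scale, gt[2], gt[3], gt[4], gt[5] * scale)
    return replace(raster, grid=out, geotransform=new_gt, pixel_size_m=raster.pixel_size_m * scale)
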