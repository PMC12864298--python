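"""Getis-Ord Gi* hot/cold-spot analysis of change rasters.

Changed pixels are aggregated to counts on a coarse analysis grid (Gi* on raw
binary pixels is degenerate), a binary fixed-distance-band weight matrix with
self-inclusion (the starred variant) is applied, and each cell receives a
z-score classified against the usual 90/95/99 % normal thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

Z_90, Z_95, Z_99 = 1.645, 1.96, 2.576

SIGNIFICANCE_CLASSES = ("cold99", "cold95", "cold90", "ns", "hot90", "hot95", "hot99")

DEFAULT_BAND_RADIUS = 1.5  # cell units: rook + self neighbourhood


@dataclass
class HotspotGrid:
    """Counts-per-cell analysis grid derived from a binary change mask."""

    values: np.ndarray  # (rows, cols) counts
    cell_size_px: int
    z_scores: np.ndarray | None = None
    significance: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.values.size


def aggregate_changes_to_grid(change_mask: np.ndarray, cell_size_px: int) -> HotspotGrid:
    """Bin changed pixels (as points at their centres) into a regular grid.

    Cell ``(i, j)`` counts the changed pixels inside the corresponding
    ``cell_size_px`` block; edge cells cover the remainder.  Total counts are
    conserved.  An empty mask yields an all-zero grid with a warning.
    """
    mask = np.asarray(change_mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("change mask must be binary")
        mask = mask.astype(bool)
    if cell_size_px < 1:
        raise ValueError("cell_size_px must be >= 1")
    if not mask.any():
        warnings.warn("empty change mask: hotspot grid is all zeros", stacklevel=2)
    h, w = mask.shape
    n_rows = int(np.ceil(h / cell_size_px))
    n_cols = int(np.ceil(w / cell_size_px))
    rows, cols = np.nonzero(mask)
    values = np.zeros((n_rows, n_cols), dtype=float)
    np.add.at(values, (rows // cell_size_px, cols // cell_size_px), 1.0)
    return HotspotGrid(values=values, cell_size_px=cell_size_px)


def _band_kernel(band_radius: float) -> np.ndarray:
    r = int(np.floor(band_radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2 <= band_radius**2).astype(float)


def gi_star(
    values: np.ndarray | HotspotGrid, band_radius: float = DEFAULT_BAND_RADIUS
) -> np.ndarray:
    """Per-cell Gi* z-scores under binary distance-band weights with self.

    For cell i with weights w_ij in {0, 1} (w_ii = 1, neighbours within
    ``band_radius`` cell units):

        Gi* = (sum_j w_ij x_j - Xbar W_i)
              / (S * sqrt((n sum_j w_ij^2 - W_i^2) / (n - 1)))

    with W_i = sum_j w_ij, Xbar the global mean and S the population standard
    deviation.  A constant field (S = 0) returns all zeros by convention.
    """
    if band_radius <= 0:
        raise ValueError("band_radius must be positive")
    x = values.values if isinstance(values, HotspotGrid) else np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 cells")
    kernel = _band_kernel(band_radius)
    wx = ndimage.convolve(x, kernel, mode="constant", cval=0.0)
    wi = ndimage.convolve(np.ones_like(x), kernel, mode="constant", cval=0.0)
    xbar = x.sum() / n
    s = np.sqrt((x**2).sum() / n - xbar**2)
    if s == 0:
        z = np.zeros_like(x)
    else:
        denom = s * np.sqrt((n * wi - wi**2) / (n - 1))  # sum w^2 = W_i for binary weights
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(denom > 0, (wx - xbar * wi) / denom, 0.0)
    if isinstance(values, HotspotGrid):
        values.z_scores = z
    return z


def classify_significance(z_scores: np.ndarray) -> np.ndarray:
    """Map z-scores to {cold99, cold95, cold90, ns, hot90, hot95, hot99}."""
    z = np.asarray(z_scores, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    out = np.full(z.shape, "ns", dtype="<U6")
    out[z >= Z_90] = "hot90"
    out[z >= Z_95] = "hot95"
    out[z >= Z_99] = "hot99"
    out[z <= -Z_90] = "cold90"
    out[z <= -Z_95] = "cold95"
    out[z <= -Z_99] = "cold99"
    return out


def fdr_threshold(z_scores: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Optional Benjamini-Hochberg correction: boolean mask of significant cells.

    Off by default in the pipeline; provided for exploratory use.
    """
    z = np.asarray(z_scores, dtype=float).ravel()
    p = 2.0 * stats.norm.sf(np.abs(z))
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    cutoff_idx = np.nonzero(passed)[0]
    keep = np.zeros(m, dtype=bool)
    if cutoff_idx.size:
        keep[order[: cutoff_idx.max() + 1]] = True
    return keep.reshape(np.asarray(z_scores).shape)


def hotspot_analysis(
    change_mask: np.ndarray,
    cell_size_px: int,
    band_radius: float = DEFAULT_BAND_RADIUS,
) -> HotspotGrid:
    """Aggregate, score, and classify a change mask in one call."""
    grid = aggregate_changes_to_grid(change_mask, cell_size_px)
    grid.z_scores = gi_star(grid.values, band_radius)
    grid.significance = classify_significance(grid.z_scores)
    return grid


def to_geojson(
    grid: HotspotGrid, pixel_size_m: float, origin: tuple = (0.0, 0.0)
) -> dict:
    """Export z-scored cells as a GeoJSON FeatureCollection of cell centres."""
    if grid.z_scores is None:
        raise ValueError("run gi_star first")
    sig = grid.significance if grid.significance is not None else classify_significance(grid.z_scores)
    x0, y0 = origin
    cell_m = grid.cell_size_px * pixel_size_m
    features = []
    for i in range(grid.values.shape[0]):
        for j in range(grid.values.shape[1]):
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [x0 + (j + 0.5) * cell_m, y0 - (i + 0.5) * cell_m],
                    },
                    "properties": {
                        "count": float(grid.values[i, j]),
                        "z": float(grid.z_scores[i, j]),
                        "significance": str(sig[i, j]),
                    },
                }
            )
    return {"type": "FeatureCollection", "features": features}
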