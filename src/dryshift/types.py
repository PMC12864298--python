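"""Core raster containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Default geotransform for synthetic scenes: (x0, px_w, 0, y0, 0, -px_h),
#: top-left origin, pixel-is-area, north-up.
DEFAULT_CRS = "EPSG:32618"


def default_geotransform(pixel_size_m: float, x0: float = 0.0, y0: float = 0.0):
    return (x0, float(pixel_size_m), 0.0, y0, 0.0, -float(pixel_size_m))


@dataclass
class SceneRaster:
    """Georeferenced multi-band grid (rows x cols x bands).

    Parameters
    ----------
    grid
        Rank-3 float array ``(rows, cols, bands)``.
    band_names
        One name per band.
    pixel_size_m
        Ground pixel size in metres (square pixels).
    geotransform
        GDAL-style 6-tuple, top-left origin, pixel-is-area.
    crs
        Coordinate reference system identifier.
    nodata
        Sentinel value marking invalid pixels, or ``None``.
    """

    grid: np.ndarray
    band_names: list[str]
    pixel_size_m: float
    geotransform: tuple = None
    crs: str = DEFAULT_CRS
    nodata: float | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be rank-3 (rows, cols, bands), got shape {self.grid.shape}")
        if self.grid.shape[2] < 1:
            raise ValueError("raster needs at least one band")
        if len(self.band_names) != self.grid.shape[2]:
            raise ValueError(
                f"{len(self.band_names)} band names for {self.grid.shape[2]} bands"
            )
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        if self.geotransform is None:
            self.geotransform = default_geotransform(self.pixel_size_m)
        valid = self.valid_mask()
        if not np.all(np.isfinite(self.grid[valid])):
            raise ValueError("grid contains non-finite values outside nodata")

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    @property
    def n_bands(self) -> int:
        return self.grid.shape[2]

    def band(self, name: str) -> np.ndarray:
        """Return the 2-D array of the named band."""
        try:
            idx = self.band_names.index(name)
        except ValueError:
            raise KeyError(f"band {name!r} not present; have {self.band_names}") from None
        return self.grid[:, :, idx]

    def valid_mask(self) -> np.ndarray:
        """Boolean (rows, cols, bands) mask of non-nodata samples."""
        if self.nodata is None:
            return np.ones(self.grid.shape, dtype=bool)
        return self.grid != self.nodata

    def with_grid(self, grid: np.ndarray, band_names: list[str] | None = None) -> "SceneRaster":
        return replace(
            self, grid=grid, band_names=list(band_names or self.band_names)
        )


@dataclass
class LabelRaster:
    """Single-band categorical grid with the same georeferencing contract."""

    labels: np.ndarray
    pixel_size_m: float
    geotransform: tuple = None
    crs: str = DEFAULT_CRS
    nodata: int = 255

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        if self.geotransform is None:
            self.geotransform = default_geotransform(self.pixel_size_m)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def valid_mask(self) -> np.ndarray:
        return self.labels != self.nodata

    def class_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.valid_mask()])

    def with_labels(self, labels: np.ndarray) -> "LabelRaster":
        return replace(self, labels=labels)
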