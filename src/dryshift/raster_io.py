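"""GeoTIFF-style raster I/O backed by tifffile plus a JSON georeferencing sidecar.

The full GDAL stack is not a dependency; rasters are stored as plain TIFFs
with band interleave and an ``<name>.aux.json`` sidecar carrying the
geotransform, CRS, band names, pixel size and nodata value.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from dryshift.types import LabelRaster, SceneRaster


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".aux.json")


def write_scene(path, raster: SceneRaster) -> None:
    path = Path(path)
    tifffile.imwrite(path, raster.grid.astype(np.float32))
    meta = {
        "kind": "scene",
        "band_names": raster.band_names,
        "pixel_size_m": raster.pixel_size_m,
        "geotransform": list(raster.geotransform),
        "crs": raster.crs,
        "nodata": raster.nodata,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def write_labels(path, labels: LabelRaster) -> None:
    path = Path(path)
    tifffile.imwrite(path, labels.labels.astype(np.uint8))
    meta = {
        "kind": "labels",
        "pixel_size_m": labels.pixel_size_m,
        "geotransform": list(labels.geotransform),
        "crs": labels.crs,
        "nodata": int(labels.nodata),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_scene(path) -> SceneRaster:
    path = Path(path)
    grid = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") != "scene":
        raise ValueError(f"{path} is not a scene raster")
    return SceneRaster(
        grid=np.asarray(grid, dtype=float),
        band_names=meta["band_names"],
        pixel_size_m=meta["pixel_size_m"],
        geotransform=tuple(meta["geotransform"]),
        crs=meta["crs"],
        nodata=meta["nodata"],
    )


def read_labels(path) -> LabelRaster:
    path = Path(path)
    labels = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") != "labels":
        raise ValueError(f"{path} is not a label raster")
    return LabelRaster(
        labels=np.asarray(labels, dtype=np.uint8),
        pixel_size_m=meta["pixel_size_m"],
        geotransform=tuple(meta["geotransform"]),
        crs=meta["crs"],
        nodata=meta["nodata"],
    )
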