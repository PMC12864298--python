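"""Synthetic paired optical/SAR scene generation with known labels.

Scenes emulate a 5 m four-band optical sensor (Red, Green, Blue, NIR) and a
10 m four-band SAR backscatter composite (HH, HV, VV, VH) over a categorical
land-cover field, so every downstream stage can be exercised without external
imagery.  The label field is a smoothed Gaussian random field quantised into
classes; optical pixels get additive Gaussian noise, SAR pixels multiplicative
gamma speckle with ``L`` looks (mean 1, variance 1/L).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from dryshift.types import LabelRaster, SceneRaster, default_geotransform

OPTICAL_BANDS = ["Red", "Green", "Blue", "NIR"]
SAR_BANDS = ["HH", "HV", "VV", "VH"]

#: Default class roster: 0 other, 1 urban, 2 agriculture, 3 forest, 4 water,
#: 5 tropical dry forest.  Spectra chosen for separability, not realism.
DEFAULT_CLASS_NAMES = ["other", "urban", "agriculture", "forest", "water", "tdf"]

_DEFAULT_OPTICAL_MEANS = np.array(
    [
        [0.45, 0.40, 0.35, 0.45],  # other / bare soil
        [0.60, 0.58, 0.55, 0.50],  # urban
        [0.25, 0.45, 0.20, 0.65],  # agriculture
        [0.08, 0.25, 0.10, 0.85],  # forest
        [0.05, 0.08, 0.12, 0.04],  # water
        [0.15, 0.32, 0.14, 0.55],  # tdf
    ]
)

_DEFAULT_SAR_MEANS = np.array(
    [
        [0.10, 0.030, 0.12, 0.035],
        [0.60, 0.200, 0.65, 0.220],
        [0.15, 0.050, 0.18, 0.060],
        [0.30, 0.120, 0.32, 0.130],
        [0.02, 0.005, 0.025, 0.006],
        [0.22, 0.080, 0.24, 0.090],
    ]
)

OPTICAL_PIXEL_SIZE_M = 5.0
SAR_PIXEL_SIZE_M = 10.0


def default_class_spectra(n_classes: int = 6) -> np.ndarray:
    """Per-class mean vectors: 4 optical reflectances then 4 SAR backscatters."""
    if n_classes > 6:
        raise ValueError("default spectra are defined for at most 6 classes")
    return np.concatenate(
        [_DEFAULT_OPTICAL_MEANS[:n_classes], _DEFAULT_SAR_MEANS[:n_classes]], axis=1
    )


@dataclass
class SyntheticSceneConfig:
    """Parameters of a synthetic paired scene.

    ``class_spectra`` rows hold the per-class mean over 4 optical bands
    (reflectance in [0, 1]) followed by 4 SAR bands (linear backscatter > 0).
    ``speckle_looks`` is the gamma look count L; set ``speckle`` False to
    disable multiplicative noise entirely.
    """

    height_px: int = 128
    width_px: int = 128
    n_classes: int = 6
    class_spectra: np.ndarray = None
    optical_noise_sd: float = 0.02
    speckle_looks: int = 4
    speckle: bool = True
    smoothness: float = 8.0
    change_fraction: float = 0.0
    seed: int = 0
    min_class_fraction: float | None = 0.01

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.height_px % 2 or self.width_px % 2:
            raise ValueError("height_px and width_px must be divisible by 2 (SAR grid is half resolution)")
        if self.class_spectra is None:
            self.class_spectra = default_class_spectra(self.n_classes)
        self.class_spectra = np.asarray(self.class_spectra, dtype=float)
        if self.class_spectra.shape != (self.n_classes, 8):
            raise ValueError(
                f"class_spectra must be ({self.n_classes}, 8), got {self.class_spectra.shape}"
            )
        if np.any(self.class_spectra[:, 4:] <= 0):
            raise ValueError("SAR class means must be strictly positive")
        if not 0.0 <= self.change_fraction <= 1.0:
            raise ValueError("change_fraction must lie in [0, 1]")
        if self.speckle_looks < 1:
            raise ValueError("speckle_looks must be >= 1")
        if self.optical_noise_sd < 0:
            raise ValueError("optical_noise_sd must be non-negative")

    @property
    def optical_means(self) -> np.ndarray:
        return self.class_spectra[:, :4]

    @property
    def sar_means(self) -> np.ndarray:
        return self.class_spectra[:, 4:]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(n)]


def generate_label_map(config: SyntheticSceneConfig, seed: int) -> LabelRaster:
    """Draw a categorical label field as a quantile-thresholded smoothed noise field.

    White noise is smoothed with a Gaussian kernel of width ``config.smoothness``
    and cut at equal quantiles into ``n_classes`` bins, yielding contiguous
    blobs with roughly equal class shares (each class >= 1% by construction).
    Deterministic in ``(config, seed)``.
    """
    if config.n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((config.height_px, config.width_px))
    if config.smoothness > 0:
        fld = ndimage.gaussian_filter(noise, sigma=config.smoothness, mode="reflect")
    else:
        fld = noise
    # Equal-quantile cuts give near-equal class shares regardless of smoothing.
    qs = np.quantile(fld, np.linspace(0, 1, config.n_classes + 1)[1:-1])
    labels = np.searchsorted(qs, fld, side="right").astype(np.uint8)
    if config.min_class_fraction is not None:
        floor = config.min_class_fraction * labels.size
        counts = np.bincount(labels.ravel(), minlength=config.n_classes)
        if np.any(counts < floor):
            warnings.warn("class share fell below the configured floor", stacklevel=2)
    return LabelRaster(labels=labels, pixel_size_m=OPTICAL_PIXEL_SIZE_M)


def render_scene(
    labels: LabelRaster, config: SyntheticSceneConfig, seed: int
) -> tuple[SceneRaster, SceneRaster]:
    """Render a label map into a fine optical raster and a coarse SAR raster.

    Optical: per-pixel class mean + N(0, optical_noise_sd), clipped to [0, 1],
    at the label grid resolution.  SAR: the class backscatter field is averaged
    over 2x2 blocks onto the half-resolution grid, then multiplied by
    Gamma(L, 1/L) speckle (unit mean, variance 1/L) when speckle is enabled.
    """
    lab = labels.labels
    if lab.max() >= config.n_classes:
        raise ValueError(
            f"label id {int(lab.max())} has no spectra (n_classes={config.n_classes})"
        )
    rng = np.random.default_rng(seed)
    h, w = lab.shape

    optical = config.optical_means[lab].astype(float)
    if config.optical_noise_sd > 0:
        optical = optical + rng.normal(0.0, config.optical_noise_sd, optical.shape)
    optical = np.clip(optical, 0.0, 1.0)

    sar_fine = config.sar_means[lab].astype(float)
    sar = sar_fine.reshape(h // 2, 2, w // 2, 2, 4).mean(axis=(1, 3))
    if config.speckle:
        looks = config.speckle_looks
        speckle = rng.gamma(shape=looks, scale=1.0 / looks, size=sar.shape)
        sar = sar * speckle

    gt_fine = labels.geotransform
    gt_coarse = (gt_fine[0], gt_fine[1] * 2, gt_fine[2], gt_fine[3], gt_fine[4], gt_fine[5] * 2)
    optical_raster = SceneRaster(
        grid=optical,
        band_names=list(OPTICAL_BANDS),
        pixel_size_m=labels.pixel_size_m,
        geotransform=gt_fine,
        crs=labels.crs,
    )
    sar_raster = SceneRaster(
        grid=sar,
        band_names=list(SAR_BANDS),
        pixel_size_m=labels.pixel_size_m * 2,
        geotransform=gt_coarse,
        crs=labels.crs,
    )
    return optical_raster, sar_raster


def inject_change(
    labels_t1: LabelRaster,
    from_class: int,
    to_class: int,
    change_fraction: float,
    seed: int,
) -> tuple[LabelRaster, np.ndarray]:
    """Relabel a spatially contiguous share of ``from_class`` pixels to ``to_class``.

    The changed region is the ``round(change_fraction * count)`` pixels of
    ``from_class`` nearest (Euclidean) to a randomly chosen seed pixel of that
    class, producing a compact blob.  Returns the new label map and a boolean
    truth mask over exactly the changed pixels; everything else is untouched.
    """
    if not 0.0 <= change_fraction <= 1.0:
        raise ValueError("change_fraction must lie in [0, 1]")
    lab = labels_t1.labels
    rows, cols = np.nonzero(lab == from_class)
    if rows.size == 0:
        raise ValueError(f"from_class {from_class} not present in labels")
    mask = np.zeros(lab.shape, dtype=bool)
    n_target = int(round(change_fraction * rows.size))
    if n_target > 0:
        rng = np.random.default_rng(seed)
        centre = rng.integers(rows.size)
        d2 = (rows - rows[centre]) ** 2 + (cols - cols[centre]) ** 2
        order = np.argsort(d2, kind="stable")[:n_target]
        mask[rows[order], cols[order]] = True
    out = lab.copy()
    out[mask] = to_class
    return labels_t1.with_labels(out), mask


@dataclass
class SceneEpoch:
    """One simulated acquisition date."""

    optical: SceneRaster
    sar: SceneRaster
    labels: LabelRaster
    truth_mask: np.ndarray | None = None  # None for the first epoch


@dataclass
class ChangeSpec:
    from_class: int
    to_class: int
    change_fraction: float


def generate_series(
    config: SyntheticSceneConfig,
    epochs: list[ChangeSpec | None],
    seed: int,
) -> list[SceneEpoch]:
    """Simulate a multi-date series with injected class transitions.

    ``epochs`` holds one entry per acquisition: the first entry is ignored
    (epoch 0 is rendered straight from the generated label map) and each later
    entry is either ``None`` (no change) or a :class:`ChangeSpec` applied to
    the previous epoch's labels before re-rendering with fresh noise.
    """
    if len(epochs) < 1:
        raise ValueError("need at least one epoch")
    seeds = _child_seeds(seed, 2 * len(epochs) + 1)
    labels = generate_label_map(config, seeds[0])
    series: list[SceneEpoch] = []
    for i, spec in enumerate(epochs):
        truth = None
        if i > 0:
            if spec is not None:
                labels, truth = inject_change(
                    labels, spec.from_class, spec.to_class, spec.change_fraction, seeds[2 * i]
                )
            else:
                truth = np.zeros(labels.shape, dtype=bool)
        optical, sar = render_scene(labels, config, seeds[2 * i + 1])
        series.append(SceneEpoch(optical=optical, sar=sar, labels=labels, truth_mask=truth))
    return series
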