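"""K-means-ensemble pseudo-labeling on a 10-feature pixel stack.

Three clusterer variants — uniform-random-init k-means, k-means++ seeding,
and k-means++ on the leading ``k-1`` principal components — are fitted to a
per-scene normalized feature table (6 optical features plus 4 bilinearly
up-sampled SAR features).  Each variant's clusters are mapped once to classes
by majority overlap against the labeled training subset; per-pixel majority
voting over the three mapped maps yields one-shot frozen pseudo-labels, with
three-way disagreements resolved in favour of the k-means++ variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import accuracy_score, f1_score

from dryshift import raster_prep
from dryshift.types import SceneRaster

FEATURE_NAMES = [
    "Red",
    "Green",
    "Blue",
    "NIR",
    "GNDVI",
    "NDVI",
    "VV",
    "HH",
    "VV+VH",
    "HH+HV",
]

#: SAR composite band backing each printed SAR feature name.
_SAR_FEATURE_BANDS = {"VV": "VV", "HH": "HH", "VV+VH": "VH", "HH+HV": "HV"}

VARIANTS = ("kmeans", "kmeans_pp", "pca_kmeans")
PREFERRED_VARIANT = "kmeans_pp"  # wins three-way vote disagreements

KMEANS_MAX_ITER = 300
KMEANS_TOL = 1e-4
KMEANS_RANDOM_RESTARTS = 10  # uniform-init variant lacks seeding robustness


@dataclass
class FeatureTable:
    """Pixels x 10 feature matrix with provenance of the source grid."""

    matrix: np.ndarray
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    grid_shape: tuple = None  # (rows, cols) of the fine grid

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.feature_names):
            raise ValueError(
                f"matrix must be (pixels, {len(self.feature_names)}), got {self.matrix.shape}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("features must be finite")

    def __len__(self) -> int:
        return self.matrix.shape[0]


def build_feature_table(optical: SceneRaster, sar: SceneRaster) -> FeatureTable:
    """Stack optical+index bands with bilinearly up-sampled SAR into 10 features.

    ``optical`` must carry Red, Green, Blue, NIR, NDVI, GNDVI at the fine
    resolution; ``sar`` carries the four backscatter composites at half
    resolution and is up-sampled x2 with bilinear interpolation.  Every
    feature is min-max normalized to [0, 1] per scene (constant features map
    to 0).
    """
    for name in ("Red", "Green", "Blue", "NIR", "NDVI", "GNDVI"):
        if name not in optical.band_names:
            raise ValueError(f"missing optical band {name!r}")
    for band in set(_SAR_FEATURE_BANDS.values()):
        if band not in sar.band_names:
            raise ValueError(f"missing SAR band {band!r}")
    h, w = optical.grid.shape[:2]
    sar_up = raster_prep.resample(sar, 2, "bilinear_up")
    if sar_up.grid.shape[:2] != (h, w):
        raise ValueError("optical and SAR rasters are not co-registered at 2:1")
    columns = []
    for name in FEATURE_NAMES:
        if name in _SAR_FEATURE_BANDS:
            col = sar_up.band(_SAR_FEATURE_BANDS[name])
        else:
            col = optical.band(name)
        col = col.astype(float).ravel()
        lo, hi = col.min(), col.max()
        # near-constant spans (e.g. float jitter from interpolating a constant
        # band) must not be amplified to full range
        if hi - lo > 1e-9 * max(1.0, abs(hi), abs(lo)):
            col = (col - lo) / (hi - lo)
        else:
            col = np.zeros_like(col)
        columns.append(col)
    return FeatureTable(matrix=np.column_stack(columns), grid_shape=(h, w))


@dataclass
class ClusterEnsemble:
    """Three fitted k-means variants plus frozen cluster-to-class mappings."""

    clusterers: dict
    k: int
    seed: int
    pca: PCA | None = None
    mappings: dict = field(default_factory=dict)  # variant -> {cluster: class}

    def predict_clusters(self, features: FeatureTable | np.ndarray) -> dict:
        x = features.matrix if isinstance(features, FeatureTable) else np.asarray(features)
        out = {}
        for name, km in self.clusterers.items():
            xv = self.pca.transform(x) if name == "pca_kmeans" else x
            out[name] = km.predict(xv)
        return out

    def predict_classes(self, features: FeatureTable | np.ndarray) -> dict:
        """Apply the frozen mappings; never re-estimates the cluster->class table."""
        if set(self.mappings) != set(self.clusterers):
            raise RuntimeError("cluster->class mappings have not been fitted for all variants")
        clusters = self.predict_clusters(features)
        return {
            name: apply_mapping(assign, self.mappings[name])
            for name, assign in clusters.items()
        }


def fit_cluster_ensemble(
    features: FeatureTable | np.ndarray, k: int = 6, seed: int = 0
) -> ClusterEnsemble:
    """Fit the three k-means variants on the same feature matrix.

    (a) k-means with uniform-random init (10 restarts), (b) k-means++
    seeding, (c) k-means++ in the space of the first ``k - 1`` principal
    components.  All variants share ``k`` and are deterministic under
    ``seed``.
    """
    x = features.matrix if isinstance(features, FeatureTable) else np.asarray(features, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if x.shape[0] < k:
        raise ValueError(f"need at least k={k} pixels, got {x.shape[0]}")
    common = dict(n_clusters=k, max_iter=KMEANS_MAX_ITER, tol=KMEANS_TOL)
    km_plain = KMeans(
        init="random", n_init=KMEANS_RANDOM_RESTARTS, random_state=seed, **common
    ).fit(x)
    km_pp = KMeans(init="k-means++", n_init=1, random_state=seed + 1, **common).fit(x)
    pca = PCA(n_components=min(k - 1, x.shape[1]), random_state=seed + 2).fit(x)
    km_pca = KMeans(init="k-means++", n_init=1, random_state=seed + 3, **common).fit(
        pca.transform(x)
    )
    return ClusterEnsemble(
        clusterers={"kmeans": km_plain, "kmeans_pp": km_pp, "pca_kmeans": km_pca},
        k=k,
        seed=seed,
        pca=pca,
    )


def map_clusters_to_classes(
    assignments: np.ndarray, reference_labels: np.ndarray, k: int | None = None
) -> dict:
    """Majority-overlap mapping from cluster ids to class ids.

    Built from the labeled training subset only and frozen afterwards.  Ties
    go to the lowest class id; clusters with no labeled pixels map to class 0
    with a warning.
    """
    assignments = np.asarray(assignments).ravel()
    reference_labels = np.asarray(reference_labels).ravel()
    if assignments.shape != reference_labels.shape:
        raise ValueError("assignments and labels must be aligned")
    k = int(assignments.max()) + 1 if k is None else k
    n_classes = int(reference_labels.max()) + 1
    mapping = {}
    for c in range(k):
        sel = assignments == c
        if not sel.any():
            warnings.warn(f"cluster {c} has no labeled pixels; mapped to class 0", stacklevel=2)
            mapping[c] = 0
            continue
        counts = np.bincount(reference_labels[sel], minlength=n_classes)
        mapping[c] = int(np.argmax(counts))  # argmax takes the lowest id on ties
    return mapping


def apply_mapping(assignments: np.ndarray, mapping: dict) -> np.ndarray:
    lut = np.zeros(max(mapping) + 1, dtype=np.int64)
    for c, cls in mapping.items():
        lut[c] = cls
    return lut[np.asarray(assignments)]


def fit_cluster_mappings(
    ensemble: ClusterEnsemble,
    features: FeatureTable | np.ndarray,
    reference_labels: np.ndarray,
) -> ClusterEnsemble:
    """Estimate and freeze the cluster->class mapping for every variant."""
    clusters = ensemble.predict_clusters(features)
    ensemble.mappings = {
        name: map_clusters_to_classes(assign, reference_labels, k=ensemble.k)
        for name, assign in clusters.items()
    }
    return ensemble


def vote_pseudolabels(
    map_kmeans: np.ndarray, map_kmeans_pp: np.ndarray, map_pca_kmeans: np.ndarray
) -> np.ndarray:
    """Per-pixel 2-of-3 majority over the mapped class maps.

    Three-way disagreements fall back to the k-means++ map (the variant
    treated as most reliable).  Pseudo-labels are produced once and frozen;
    no confidence filtering is applied.
    """
    a = np.asarray(map_kmeans)
    b = np.asarray(map_kmeans_pp)
    c = np.asarray(map_pca_kmeans)
    if not (a.shape == b.shape == c.shape):
        raise ValueError("class maps are misaligned")
    out = b.copy()  # k-means++ wins full disagreement
    agree_ac = a == c
    out = np.where(agree_ac, a, out)  # a==c outvotes b; a==b or b==c keep b
    return out


def generate_pseudolabels(
    ensemble: ClusterEnsemble, features: FeatureTable
) -> np.ndarray:
    """End-to-end: mapped per-variant maps -> majority vote -> label grid."""
    mapped = ensemble.predict_classes(features)
    flat = vote_pseudolabels(
        mapped["kmeans"], mapped["kmeans_pp"], mapped["pca_kmeans"]
    )
    if features.grid_shape is not None:
        return flat.reshape(features.grid_shape)
    return flat


def evaluate_clustering(
    mapped_predictions: np.ndarray, truth_labels: np.ndarray
) -> tuple[float, float]:
    """Overall pixel accuracy and unweighted class-mean (macro) F1."""
    pred = np.asarray(mapped_predictions).ravel()
    truth = np.asarray(truth_labels).ravel()
    if pred.shape != truth.shape:
        raise ValueError("maps are misaligned")
    if pred.size == 0:
        raise ValueError("no valid pixels to evaluate")
    return (
        float(accuracy_score(truth, pred)),
        float(f1_score(truth, pred, average="macro")),
    )
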