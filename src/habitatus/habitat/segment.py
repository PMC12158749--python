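"""K-means habitat segmentation with validity-index k selection.

Channels are z-scored per lesion, K-means (k-means++ init, 10 restarts)
is run for each candidate k, and each clustering is scored with the five
validity indices. The selected k maximises a rank aggregate of the
indices with interior optima — Calinski-Harabasz and separation (higher
better) and Davies-Bouldin (lower better); inertia and mean
intra-cluster distance decrease monotonically in k and therefore do not
vote. Ties go to the smaller k.

Habitat labels are renumbered canonically by ascending mean intensity
(image brightness for BMUS, stiffness for SWE) so "habitat 1" is
comparable across lesions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .features import PixelFeatureStack
from .quality import ClusterQuality, cluster_quality


@dataclass
class HabitatResult:
    label_map: np.ndarray  # 0 background, 1..k inside the ROI
    selected_k: int
    quality_curve: list = field(default_factory=list)
    modality: str = ""


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def select_k(curve: list[ClusterQuality]) -> int:
    """Rank-aggregation vote over CH (high), separation (high), DBI (low)."""
    ch = np.array([q.ch for q in curve])
    sep = np.array([q.separation for q in curve])
    dbi = np.array([q.dbi for q in curve])
    # replace +inf CH sentinels by the max finite value for ranking
    finite = np.isfinite(ch)
    if not finite.all():
        ch = np.where(finite, ch, (ch[finite].max() if finite.any() else 0.0) + 1.0)
    score = rankdata(ch) + rankdata(sep) + rankdata(-dbi)  # higher = better
    best = np.flatnonzero(score == score.max())
    ks = np.array([q.k for q in curve])
    return int(ks[best].min())


def segment_habitats(
    stack: PixelFeatureStack,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    fixed_k: int | None = None,
    intensity: np.ndarray | None = None,
    image_shape: tuple[int, int] | None = None,
    n_restarts: int = 10,
    modality: str = "",
) -> HabitatResult:
    """Cluster a lesion's pixel-feature stack into habitats.

    Parameters
    ----------
    stack : per-pixel clustering features.
    k_range : inclusive candidate range for the number of clusters.
    fixed_k : bypass selection and cluster at exactly this k (used when a
        cohort-level habitat count fixes the feature-table schema).
    intensity : per-pixel values (aligned with ``stack.pixel_index``) used
        for canonical label ordering; defaults to the mean feature value.
    image_shape : shape of the output label map; inferred from the pixel
        index when omitted.
    """
    X = stack.features
    n = X.shape[0]
    if image_shape is None:
        image_shape = (
            int(stack.pixel_index[:, 0].max()) + 1,
            int(stack.pixel_index[:, 1].max()) + 1,
        )
    if intensity is None:
        intensity = X.mean(axis=1)
    intensity = np.asarray(intensity, dtype=float)

    Z = _standardize(X)
    n_distinct = len(np.unique(np.round(Z, 12), axis=0))
    label_map = np.zeros(image_shape, dtype=int)
    rr, cc = stack.pixel_index[:, 0], stack.pixel_index[:, 1]

    if n_distinct < 2:
        warnings.warn(
            "all feature vectors identical; emitting a single habitat",
            stacklevel=2,
        )
        label_map[rr, cc] = 1
        return HabitatResult(label_map, 1, [], modality)

    if fixed_k is not None:
        ks = [min(fixed_k, n_distinct)]
    else:
        k_lo, k_hi = k_range
        k_hi = min(k_hi, n_distinct, n)
        k_lo = min(k_lo, k_hi)
        ks = list(range(k_lo, k_hi + 1))

    curve: list[ClusterQuality] = []
    fits = {}
    for k in ks:
        if k < 2:
            label_map[rr, cc] = 1
            return HabitatResult(label_map, 1, [], modality)
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=n_restarts,
            max_iter=300,
            tol=1e-4,
            random_state=seed,
        ).fit(Z)
        fits[k] = km
        curve.append(cluster_quality(Z, km.labels_, km.cluster_centers_))

    k_star = ks[0] if fixed_k is not None else select_k(curve)
    labels = fits[k_star].labels_

    # canonical renumbering by ascending mean intensity
    means = np.array([intensity[labels == i].mean() for i in range(k_star)])
    order = np.argsort(means, kind="stable")
    rank_of = np.empty(k_star, dtype=int)
    rank_of[order] = np.arange(k_star)
    label_map[rr, cc] = rank_of[labels] + 1
    return HabitatResult(label_map, int(k_star), curve, modality)
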