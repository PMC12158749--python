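"""Cluster-validity indices used to choose the number of habitats.

Five indices are computed from a clustered point set: Calinski-Harabasz
score, inertia (within-cluster SSE), Davies-Bouldin index, separation
(mean between-centroid distance) and mean intra-cluster distance, with

    CH   = Tr(B_k)/Tr(W_k) * (N-k)/(k-1)
    DBI  = 1/k * sum_i max_{j!=i} (sigma_i + sigma_j) / d(mu_i, mu_j)
    Sep  = 2/(k(k-1)) * sum_{i<j} d(mu_i, mu_j)
    MID  = 1/N * sum_i (1/|C_i|) sum_{x in C_i} ||x - mu_i||

where sigma_i is the average distance of cluster i's points to its
centroid mu_i. Note the mean intra-cluster distance divides the sum of
per-cluster averages by N (not k): it is reproduced exactly as printed,
so its scale shrinks as k grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ClusterQuality:
    k: int
    ch: float
    inertia: float
    dbi: float
    separation: float
    mean_intra: float


def cluster_quality(points, labels, centroids=None) -> ClusterQuality:
    """Evaluate the five indices for one clustering.

    Parameters
    ----------
    points : (n, d) feature vectors.
    labels : (n,) integer cluster assignment; every cluster non-empty.
    centroids : optional (k, d) centroids (e.g. from K-means). When
        omitted, cluster means are used — identical for converged K-means.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    n = len(X)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    remap = {lab: i for i, lab in enumerate(uniq)}
    lab_idx = np.array([remap[l] for l in labels])
    if centroids is None:
        mus = np.stack([X[lab_idx == i].mean(axis=0) for i in range(k)])
    else:
        mus = np.asarray(centroids, dtype=float)
        if mus.ndim == 1:
            mus = mus[:, None]
        if len(mus) != k:
            raise ValueError("centroid count does not match number of clusters")
    sizes = np.bincount(lab_idx, minlength=k)
    if (sizes == 0).any():
        raise ValueError("empty cluster")

    d_to_mu = np.linalg.norm(X - mus[lab_idx], axis=1)
    inertia = float((d_to_mu**2).sum())
    sigma = np.array([d_to_mu[lab_idx == i].mean() for i in range(k)])
    mean_intra = float(sigma.sum() / n)

    grand = X.mean(axis=0)
    tr_b = float((sizes * ((mus - grand) ** 2).sum(axis=1)).sum())
    if inertia <= 0:
        ch = float("inf") if tr_b > 0 else 0.0
    else:
        ch = tr_b / inertia * (n - k) / (k - 1)

    cd = np.linalg.norm(mus[:, None, :] - mus[None, :, :], axis=2)
    iu = np.triu_indices(k, 1)
    separation = float(2.0 / (k * (k - 1)) * cd[iu].sum())

    with np.errstate(divide="ignore"):
        ratio = (sigma[:, None] + sigma[None, :]) / np.where(cd > 0, cd, np.inf)
    np.fill_diagonal(ratio, -np.inf)
    dbi = float(ratio.max(axis=1).mean())

    return ClusterQuality(
        k=k,
        ch=float(ch),
        inertia=inertia,
        dbi=dbi,
        separation=separation,
        mean_intra=mean_intra,
    )
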