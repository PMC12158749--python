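"""Per-pixel clustering features for habitat segmentation.

For every ROI pixel, ten channels are computed over its window-by-window
neighbourhood intersected with the ROI:

* six GLCM statistics (contrast, dissimilarity, homogeneity, energy,
  correlation, angular second moment) from a symmetric, normalised
  co-occurrence matrix of the quantised image, pooled over the four
  distance-1 directions;
* Shannon entropy of the quantised gray-level histogram;
* mean and standard deviation of the uniform local-binary-pattern code;
* the windowed mean of the grayscale morphological closing (closing_mean).

Everything is vectorised: pair/level indicator stacks are box-filtered
once, so cost is O(levels^2 * pixels) rather than per-pixel GLCM builds.

Boundary convention: a co-occurring pair is attributed to its anchor
pixel; it contributes to a pixel's matrix when the anchor lies in the
pixel's window and both endpoints lie in the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.feature import local_binary_pattern
from skimage.morphology import closing, disk

CHANNELS = (
    "glcm_contrast",
    "glcm_dissimilarity",
    "glcm_homogeneity",
    "glcm_energy",
    "glcm_correlation",
    "glcm_asm",
    "shannon_entropy",
    "lbp_mean",
    "lbp_std",
    "closing_mean",
)

_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class PixelFeatureStack:
    """Feature vectors for every ROI pixel, plus their image coordinates."""

    features: np.ndarray  # (n_pixels, n_channels)
    channels: tuple
    window: int
    pixel_index: np.ndarray  # (n_pixels, 2) of (row, col)

    def __post_init__(self):
        if self.features.shape[0] != self.pixel_index.shape[0]:
            raise ValueError("features and pixel_index disagree on pixel count")
        if not np.isfinite(self.features).all():
            raise ValueError("feature stack contains non-finite values")


def _box_sum(a: np.ndarray, window: int) -> np.ndarray:
    """Windowed sum with zero padding (spatial axes last)."""
    size = (1,) * (a.ndim - 2) + (window, window)
    return uniform_filter(a, size=size, mode="constant", cval=0.0) * (window**2)


def _quantize(image: np.ndarray, roi: np.ndarray, levels: int) -> np.ndarray:
    vals = image[roi]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        return np.zeros(image.shape, dtype=np.int64)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def pixel_features(
    image: np.ndarray,
    roi: np.ndarray,
    window: int = 7,
    levels: int = 32,
) -> PixelFeatureStack:
    """Compute the ten clustering-feature channels for every ROI pixel.

    Parameters
    ----------
    image : 2-D grayscale (BMUS) or scalar stiffness (SWE) image.
    roi : binary lesion mask on the same grid.
    window : odd window size >= 3 for the local statistics.
    levels : gray-level quantisation for GLCM / entropy.
    """
    image = np.asarray(image, dtype=float)
    roi = np.asarray(roi) > 0
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if not roi.any():
        raise ValueError("ROI is empty")

    # crop to the ROI bounding box (padded) to bound the filter cost
    rows, cols = np.nonzero(roi)
    pad = window // 2 + 1
    r0, r1 = max(rows.min() - pad, 0), min(rows.max() + pad + 1, image.shape[0])
    c0, c1 = max(cols.min() - pad, 0), min(cols.max() + pad + 1, image.shape[1])
    img = image[r0:r1, c0:c1]
    m = roi[r0:r1, c0:c1]
    h, w = img.shape

    q = _quantize(img, m, levels)
    n_codes = levels * levels

    # symmetric pair-indicator stack over the four distance-1 directions
    pair_stack = np.zeros((n_codes, h, w), dtype=np.float32)
    for dr, dc in _DIRECTIONS:
        src = (slice(max(-dr, 0), h - max(dr, 0)), slice(max(-dc, 0), w - max(dc, 0)))
        dst = (slice(max(dr, 0), h + min(dr, 0)), slice(max(dc, 0), w + min(dc, 0)))
        both = m[src] & m[dst]
        ar, ac = np.nonzero(both)
        a = q[src][ar, ac]
        b = q[dst][ar, ac]
        pos = (ar + src[0].start) * w + (ac + src[1].start)
        flat = pair_stack.reshape(n_codes, -1)
        np.add.at(flat, (a * levels + b, pos), 1.0)
        np.add.at(flat, (b * levels + a, pos), 1.0)

    pair_counts = _box_sum(pair_stack, window)  # (codes, h, w)
    rr, cc = np.nonzero(m)
    P = pair_counts[:, rr, cc].astype(np.float64)  # (codes, n_pix)
    totals = P.sum(axis=0)
    has_pairs = totals > 0
    P[:, has_pairs] /= totals[has_pairs]
    P = P.reshape(levels, levels, -1)

    i_idx = np.arange(levels, dtype=float)
    diff = i_idx[:, None] - i_idx[None, :]
    contrast = np.tensordot(diff**2, P, axes=([0, 1], [0, 1]))
    dissim = np.tensordot(np.abs(diff), P, axes=([0, 1], [0, 1]))
    homog = np.tensordot(1.0 / (1.0 + diff**2), P, axes=([0, 1], [0, 1]))
    asm = (P**2).sum(axis=(0, 1))
    px = P.sum(axis=1)  # (levels, n_pix)
    py = P.sum(axis=0)
    mu_x = (i_idx[:, None] * px).sum(axis=0)
    mu_y = (i_idx[:, None] * py).sum(axis=0)
    var_x = ((i_idx[:, None] - mu_x) ** 2 * px).sum(axis=0)
    var_y = ((i_idx[:, None] - mu_y) ** 2 * py).sum(axis=0)
    cross = np.einsum("i,j,ijn->n", i_idx, i_idx, P)
    denom = np.sqrt(var_x * var_y)
    correlation = np.where(denom > 1e-12, (cross - mu_x * mu_y) / np.maximum(denom, 1e-300), 0.0)
    # no-pair pixels take the constant-window limits
    asm = np.where(has_pairs, asm, 1.0)
    homog = np.where(has_pairs, homog, 1.0)
    energy = np.sqrt(asm)

    # Shannon entropy of the windowed quantised histogram (ROI-masked)
    level_stack = np.zeros((levels, h, w), dtype=np.float32)
    level_stack[q[m], rr, cc] = 1.0
    level_counts = _box_sum(level_stack, window)[:, rr, cc].astype(np.float64)
    tot = level_counts.sum(axis=0)
    p_lvl = level_counts / np.maximum(tot, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(p_lvl > 0, p_lvl * np.log2(p_lvl), 0.0).sum(axis=0)
    ent = np.clip(ent, 0.0, None)

    # uniform LBP code moments over window∩ROI (on the quantised image so
    # sub-quantum float noise does not flip neighbourhood signs)
    lbp = local_binary_pattern(q, P=8, R=1, method="uniform").astype(float)
    valid = m.astype(np.float64)
    n_valid = _box_sum(valid, window)[rr, cc]
    n_valid = np.maximum(n_valid, 1.0)
    lbp_sum = _box_sum(lbp * valid, window)[rr, cc]
    lbp_sq = _box_sum(lbp**2 * valid, window)[rr, cc]
    lbp_mean = lbp_sum / n_valid
    lbp_std = np.sqrt(np.clip(lbp_sq / n_valid - lbp_mean**2, 0.0, None))

    closed = closing(img, disk(2))
    closing_mean = _box_sum(closed * valid, window)[rr, cc] / n_valid

    feats = np.column_stack(
        [
            contrast,
            dissim,
            homog,
            energy,
            correlation,
            asm,
            ent,
            lbp_mean,
            lbp_std,
            closing_mean,
        ]
    )
    pixel_index = np.column_stack([rr + r0, cc + c0])
    return PixelFeatureStack(
        features=feats, channels=CHANNELS, window=window, pixel_index=pixel_index
    )
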