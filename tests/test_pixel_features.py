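"""Per-pixel clustering-feature stack: limits, oracles, invariants."""

import numpy as np
import pytest
from scipy.ndimage import uniform_filter

from habitatus.habitat import pixel_features
from habitatus.habitat.features import CHANNELS

IDX = {c: i for i, c in enumerate(CHANNELS)}


def test_constant_image_limits():
    img = np.full((20, 20), 7.0)
    roi = np.zeros((20, 20), bool)
    roi[4:16, 4:16] = True
    stack = pixel_features(img, roi, window=7)
    f = stack.features
    assert np.allclose(f[:, IDX["glcm_contrast"]], 0.0)
    assert np.allclose(f[:, IDX["glcm_energy"]], 1.0)
    assert np.allclose(f[:, IDX["shannon_entropy"]], 0.0)
    assert np.allclose(f[:, IDX["lbp_std"]], 0.0)
    assert np.allclose(f[:, IDX["glcm_correlation"]], 0.0)


def brute_force_glcm_stats(img, roi, center, window, levels):
    """Loop-built symmetric co-occurrence matrix for one pixel's window.

    Pairs are anchored at a pixel inside the window (window cap around
    ``center``) with both endpoints inside the ROI, pooled over the four
    distance-1 directions and symmetrised.
    """
    lo, hi = img[roi].min(), img[roi].max()
    q = np.clip(np.floor((img - lo) / (hi - lo) * levels), 0, levels - 1).astype(int)
    h, w = img.shape
    half = window // 2
    P = np.zeros((levels, levels))
    for r in range(center[0] - half, center[0] + half + 1):
        for c in range(center[1] - half, center[1] + half + 1):
            if not (0 <= r < h and 0 <= c < w and roi[r, c]):
                continue
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and roi[rr, cc]:
                    P[q[r, c], q[rr, cc]] += 1
                    P[q[rr, cc], q[r, c]] += 1
    P /= P.sum()
    i = np.arange(levels)
    d = i[:, None] - i[None, :]
    return {
        "glcm_contrast": (P * d**2).sum(),
        "glcm_dissimilarity": (P * np.abs(d)).sum(),
        "glcm_homogeneity": (P / (1 + d**2)).sum(),
        "glcm_asm": (P**2).sum(),
    }


def test_checkerboard_glcm_matches_hand_built_matrix():
    # 2-px checkerboard at two gray levels
    img = np.indices((8, 8)).sum(axis=0) % 2 * 10.0
    roi = np.ones((8, 8), bool)
    stack = pixel_features(img, roi, window=7, levels=2)
    center = (4, 4)
    row = np.flatnonzero((stack.pixel_index == center).all(axis=1))[0]
    oracle = brute_force_glcm_stats(img, roi, center, 7, 2)
    # single-precision indicator accumulation bounds agreement at ~1e-6
    for name, expected in oracle.items():
        assert stack.features[row, IDX[name]] == pytest.approx(expected, rel=1e-6)
    # axial neighbours differ, diagonal neighbours match: the contrast is the
    # fraction of differing co-occurring pairs times the squared level gap
    assert 0.4 < stack.features[row, IDX["glcm_contrast"]] < 0.6


def test_closing_mean_dominates_windowed_mean():
    rng = np.random.default_rng(5)
    img = rng.uniform(0, 100, (32, 32))
    roi = np.zeros((32, 32), bool)
    roi[6:26, 6:26] = True
    stack = pixel_features(img, roi, window=5)
    # morphological closing is extensive, so its windowed mean dominates
    win_mean = uniform_filter(img * roi, 5) * 25
    win_cnt = uniform_filter(roi.astype(float), 5) * 25
    rr, cc = stack.pixel_index.T
    expected_floor = win_mean[rr, cc] / np.maximum(win_cnt[rr, cc], 1)
    assert (stack.features[:, IDX["closing_mean"]] >= expected_floor - 1e-9).all()


@pytest.mark.parametrize("seed", range(4))
def test_feature_ranges_and_finiteness(seed):
    rng = np.random.default_rng(seed)
    img = rng.uniform(0, 255, (40, 40))
    roi = np.zeros((40, 40), bool)
    rr, cc = np.indices((40, 40))
    roi[(rr - 20) ** 2 + (cc - 20) ** 2 < 14**2] = True
    stack = pixel_features(img, roi, window=7)
    f = stack.features
    assert np.isfinite(f).all()
    assert (f[:, IDX["glcm_energy"]] >= 0).all() and (f[:, IDX["glcm_energy"]] <= 1).all()
    assert (f[:, IDX["glcm_homogeneity"]] >= 0).all() and (
        f[:, IDX["glcm_homogeneity"]] <= 1
    ).all()
    assert (np.abs(f[:, IDX["glcm_correlation"]]) <= 1 + 1e-9).all()
    assert (f[:, IDX["shannon_entropy"]] >= 0).all()
    assert f.shape == (int(roi.sum()), len(CHANNELS))


def test_window_validation_and_empty_roi():
    img = np.zeros((10, 10))
    with pytest.raises(ValueError, match="odd"):
        pixel_features(img, np.ones((10, 10), bool), window=4)
    with pytest.raises(ValueError, match="empty"):
        pixel_features(img, np.zeros((10, 10), bool), window=5)
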