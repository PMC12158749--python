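"""Texture-matrix builders: GLCM, GLRLM, GLSZM, GLDM, NGTDM.

All builders operate on a gray-level image quantised to levels 1..Ng
inside a binary region mask (level 0 marks pixels outside the region).
Conventions: 2-D, 8-connectivity / Chebyshev-distance-1 neighbourhoods,
the four distance-1 directions for GLCM and GLRLM, symmetric GLCM.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))
NEIGHBORS8 = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)
_STRUCT8 = np.ones((3, 3), dtype=bool)


def quantize(image: np.ndarray, mask: np.ndarray, bins: int = 32) -> np.ndarray:
    """Fixed-bin-count quantisation to levels 1..bins inside the mask.

    A constant region maps entirely to level 1. Pixels outside the mask
    get level 0.
    """
    q = np.zeros(image.shape, dtype=np.int64)
    vals = image[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        q[mask] = 1
        return q
    scaled = np.floor((image[mask] - lo) / (hi - lo) * bins).astype(np.int64)
    q[mask] = np.clip(scaled, 0, bins - 1) + 1
    return q


def glcm_matrix(q: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts pooled over the four directions."""
    h, w = q.shape
    P = np.zeros((n_levels, n_levels), dtype=float)
    for dr, dc in DIRECTIONS:
        src = (slice(max(-dr, 0), h - max(dr, 0)), slice(max(-dc, 0), w - max(dc, 0)))
        dst = (slice(max(dr, 0), h + min(dr, 0)), slice(max(dc, 0), w + min(dc, 0)))
        both = mask[src] & mask[dst]
        a = q[src][both] - 1
        b = q[dst][both] - 1
        np.add.at(P, (a, b), 1.0)
        np.add.at(P, (b, a), 1.0)
    return P


def _line_runs(levels: np.ndarray, out: np.ndarray) -> None:
    """Accumulate run lengths of one 1-D level sequence into out (Ng, Nr)."""
    n = levels.size
    if n == 0:
        return
    change = np.flatnonzero(np.diff(levels) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [n]))
    run_levels = levels[starts]
    run_lens = ends - starts
    keep = run_levels > 0  # level 0 = outside region
    np.add.at(out, (run_levels[keep] - 1, run_lens[keep] - 1), 1.0)


def glrlm_matrix(q: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length counts pooled over the four directions."""
    h, w = q.shape
    qm = np.where(mask, q, 0)
    max_run = max(h, w)
    R = np.zeros((n_levels, max_run), dtype=float)
    for i in range(h):  # horizontal
        _line_runs(qm[i], R)
    for j in range(w):  # vertical
        _line_runs(qm[:, j], R)
    for off in range(-h + 1, w):  # both diagonals
        _line_runs(np.diagonal(qm, offset=off), R)
        _line_runs(np.diagonal(qm[:, ::-1], offset=off), R)
    last = int(np.max(np.nonzero(R.any(axis=0))[0])) if R.any() else 0
    return R[:, : last + 1]


def glszm_matrix(q: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size counts: 8-connected components per gray level."""
    sizes_per_level = []
    max_size = 1
    for lvl in range(1, n_levels + 1):
        binim = (q == lvl) & mask
        if not binim.any():
            sizes_per_level.append(np.array([], dtype=int))
            continue
        lab, nz = ndimage.label(binim, structure=_STRUCT8)
        sizes = np.bincount(lab.ravel())[1:]
        sizes_per_level.append(sizes)
        max_size = max(max_size, int(sizes.max()))
    Z = np.zeros((n_levels, max_size), dtype=float)
    for lvl, sizes in enumerate(sizes_per_level):
        if sizes.size:
            np.add.at(Z, (lvl, sizes - 1), 1.0)
    return Z


def gldm_matrix(
    q: np.ndarray, mask: np.ndarray, n_levels: int, alpha: float = 0.0
) -> np.ndarray:
    """Dependence counts: for each region pixel, the number of 8-neighbours
    inside the region whose level differs by at most alpha, plus one (so the
    dependence index starts at 1)."""
    h, w = q.shape
    dep = np.zeros((h, w), dtype=np.int64)
    for dr, dc in NEIGHBORS8:
        src = (slice(max(-dr, 0), h - max(dr, 0)), slice(max(-dc, 0), w - max(dc, 0)))
        dst = (slice(max(dr, 0), h + min(dr, 0)), slice(max(dc, 0), w + min(dc, 0)))
        ok = mask[src] & mask[dst] & (np.abs(q[src] - q[dst]) <= alpha)
        dep[src] += ok
    D = np.zeros((n_levels, 9 + 1), dtype=float)
    np.add.at(D, (q[mask] - 1, dep[mask] + 1 - 1), 1.0)
    last = int(np.max(np.nonzero(D.any(axis=0))[0])) if D.any() else 0
    return D[:, : last + 1]


def ngtdm_table(
    q: np.ndarray, mask: np.ndarray, n_levels: int
) -> tuple[np.ndarray, np.ndarray]:
    """Return (n_i, s_i): per-level pixel counts and summed absolute
    differences from the 8-neighbourhood mean, over region pixels that
    have at least one region neighbour."""
    h, w = q.shape
    nb_sum = np.zeros((h, w), dtype=float)
    nb_cnt = np.zeros((h, w), dtype=float)
    for dr, dc in NEIGHBORS8:
        src = (slice(max(-dr, 0), h - max(dr, 0)), slice(max(-dc, 0), w - max(dc, 0)))
        dst = (slice(max(dr, 0), h + min(dr, 0)), slice(max(dc, 0), w + min(dc, 0)))
        ok = mask[dst]
        nb_sum[src] += np.where(ok, q[dst], 0)
        nb_cnt[src] += ok
    valid = mask & (nb_cnt > 0)
    diff = np.zeros((h, w), dtype=float)
    diff[valid] = np.abs(q[valid] - nb_sum[valid] / nb_cnt[valid])
    n_i = np.zeros(n_levels, dtype=float)
    s_i = np.zeros(n_levels, dtype=float)
    np.add.at(n_i, q[valid] - 1, 1.0)
    np.add.at(s_i, q[valid] - 1, diff[valid])
    return n_i, s_i
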