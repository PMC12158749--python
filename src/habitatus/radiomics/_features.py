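"""Named feature computations for each radiomics class.

Feature rosters follow the de-facto standard 2-D set: 10 shape, 18
first-order, 24 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM and 5 NGTDM features
per image band. Degenerate regions (single gray level, single pixel
zone) take their analytic limits so every feature is finite.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

_EPS = np.finfo(float).eps


# ---------------------------------------------------------------- shape


def shape_features(mask: np.ndarray) -> dict:
    """10 two-dimensional shape descriptors of the region mask."""
    mask = np.asarray(mask) > 0
    props = measure.regionprops(mask.astype(int))[0]
    pixel_surface = float(mask.sum())
    perimeter = float(props.perimeter) or _EPS
    # mesh surface from the marching-squares boundary (shoelace)
    mesh = 0.0
    for contour in measure.find_contours(np.pad(mask.astype(float), 1), 0.5):
        y, x = contour[:, 0], contour[:, 1]
        mesh += 0.5 * abs(np.dot(y, np.roll(x, 1)) - np.dot(x, np.roll(y, 1)))
    if mesh <= 0:
        mesh = pixel_surface
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    sphericity = 2.0 * np.sqrt(np.pi * mesh) / perimeter
    return {
        "MeshSurface": mesh,
        "PixelSurface": pixel_surface,
        "Perimeter": perimeter,
        "PerimeterSurfaceRatio": perimeter / mesh,
        "Sphericity": sphericity,
        "SphericalDisproportion": 1.0 / sphericity if sphericity > 0 else 0.0,
        "MaximumDiameter": float(props.feret_diameter_max),
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "Elongation": minor / major if major > 0 else 1.0,
    }


# ----------------------------------------------------------- first order


def firstorder_features(values: np.ndarray, bins: int = 32) -> dict:
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    mean = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    hist, _ = np.histogram(x, bins=bins)
    p = hist / n
    p = p[p > 0]
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    core = x[(x >= p10) & (x <= p90)]
    if sd > 0:
        z = (x - mean) / sd
        skew = float((z**3).mean())
        kurt = float((z**4).mean())  # Pearson (non-excess) kurtosis
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float((x**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(core - core.mean()).mean() if core.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": float((p**2).sum()),
    }


# ------------------------------------------------------------------ GLCM


def glcm_features(P_counts: np.ndarray) -> dict:
    P = P_counts / max(P_counts.sum(), _EPS)
    ng = P.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sig_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sig_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    d = np.abs(ii - jj)
    k_diff = np.arange(ng, dtype=float)
    p_diff = np.array([P[d == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.array([P[(ii + jj) == k].sum() for k in k_sum])

    da = (k_diff * p_diff).sum()
    nz = P > 0
    hxy = -(P[nz] * np.log2(P[nz])).sum()
    pxy = np.outer(px, py)
    ok = pxy > 0
    hxy1 = -(P[ok] * np.log2(pxy[ok])).sum()
    hxy2 = -(pxy[ok] * np.log2(pxy[ok])).sum()
    hx = -(px[px > 0] * np.log2(px[px > 0])).sum()
    hy = -(py[py > 0] * np.log2(py[py > 0])).sum()
    max_h = max(hx, hy)
    imc1 = (hxy - hxy1) / max_h if max_h > 0 else 0.0
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))

    if sig_x * sig_y > 0:
        correlation = ((ii * jj * P).sum() - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 0.0

    # MCC from the row-normalised transition kernel
    rows = px > 0
    if rows.sum() > 1:
        Psub = P[np.ix_(rows, rows)]
        pxs, pys = px[rows], py[rows]
        Q = (Psub / pxs[:, None]) @ (Psub / pys[None, :]).T
        ev = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(ev[-2].real, 0.0))) if ev.size > 1 else 1.0
    else:
        mcc = 1.0

    off = ii != jj
    return {
        "Autocorrelation": float((ii * jj * P).sum()),
        "JointAverage": float(mu_x),
        "ClusterProminence": float((((ii + jj) - mu_x - mu_y) ** 4 * P).sum()),
        "ClusterShade": float((((ii + jj) - mu_x - mu_y) ** 3 * P).sum()),
        "ClusterTendency": float((((ii + jj) - mu_x - mu_y) ** 2 * P).sum()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": float(correlation),
        "DifferenceAverage": float(da),
        "DifferenceEntropy": float(
            -(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()
        ),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": float(hxy),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((P / (1.0 + ((ii - jj) ** 2) / ng**2)).sum()),
        "Id": float((P / (1.0 + d)).sum()),
        "Idn": float((P / (1.0 + d / ng)).sum()),
        "InverseVariance": float((P[off] / (ii - jj)[off] ** 2).sum()),
        "MaximumProbability": float(P.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
        "SumSquares": float(((ii - mu_x) ** 2 * P).sum()),
        "MCC": mcc,
    }


# -------------------------------------------------- run-length / zone size


def _level_size_stats(M: np.ndarray) -> dict:
    """Shared statistics for GLRLM (runs) and GLSZM (zones)."""
    nz = max(M.sum(), _EPS)
    ng, nr = M.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, nr + 1, dtype=float)[None, :]
    row = M.sum(axis=1)
    col = M.sum(axis=0)
    p = M / nz
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    pn = p[p > 0]
    return {
        "small": float((M / j**2).sum() / nz),
        "large": float((M * j**2).sum() / nz),
        "gln": float((row**2).sum() / nz),
        "glnn": float((row**2).sum() / nz**2),
        "sizen": float((col**2).sum() / nz),
        "sizenn": float((col**2).sum() / nz**2),
        "glv": float(((i - mu_i) ** 2 * p).sum()),
        "sizev": float(((j - mu_j) ** 2 * p).sum()),
        "entropy": float(-(pn * np.log2(pn)).sum()),
        "lgl": float((M / i**2).sum() / nz),
        "hgl": float((M * i**2).sum() / nz),
        "slgl": float((M / (i**2 * j**2)).sum() / nz),
        "shgl": float((M * i**2 / j**2).sum() / nz),
        "llgl": float((M * j**2 / i**2).sum() / nz),
        "lhgl": float((M * i**2 * j**2).sum() / nz),
        "nz": float(nz),
        "np": float((M * j).sum()),
    }


def glrlm_features(R: np.ndarray) -> dict:
    s = _level_size_stats(R)
    return {
        "ShortRunEmphasis": s["small"],
        "LongRunEmphasis": s["large"],
        "GrayLevelNonUniformity": s["gln"],
        "GrayLevelNonUniformityNormalized": s["glnn"],
        "RunLengthNonUniformity": s["sizen"],
        "RunLengthNonUniformityNormalized": s["sizenn"],
        "RunPercentage": s["nz"] / max(s["np"], _EPS),
        "GrayLevelVariance": s["glv"],
        "RunVariance": s["sizev"],
        "RunEntropy": s["entropy"],
        "LowGrayLevelRunEmphasis": s["lgl"],
        "HighGrayLevelRunEmphasis": s["hgl"],
        "ShortRunLowGrayLevelEmphasis": s["slgl"],
        "ShortRunHighGrayLevelEmphasis": s["shgl"],
        "LongRunLowGrayLevelEmphasis": s["llgl"],
        "LongRunHighGrayLevelEmphasis": s["lhgl"],
    }


def glszm_features(Z: np.ndarray, n_region_pixels: int) -> dict:
    s = _level_size_stats(Z)
    return {
        "SmallAreaEmphasis": s["small"],
        "LargeAreaEmphasis": s["large"],
        "GrayLevelNonUniformity": s["gln"],
        "GrayLevelNonUniformityNormalized": s["glnn"],
        "SizeZoneNonUniformity": s["sizen"],
        "SizeZoneNonUniformityNormalized": s["sizenn"],
        "ZonePercentage": s["nz"] / max(n_region_pixels, 1),
        "GrayLevelVariance": s["glv"],
        "ZoneVariance": s["sizev"],
        "ZoneEntropy": s["entropy"],
        "LowGrayLevelZoneEmphasis": s["lgl"],
        "HighGrayLevelZoneEmphasis": s["hgl"],
        "SmallAreaLowGrayLevelEmphasis": s["slgl"],
        "SmallAreaHighGrayLevelEmphasis": s["shgl"],
        "LargeAreaLowGrayLevelEmphasis": s["llgl"],
        "LargeAreaHighGrayLevelEmphasis": s["lhgl"],
    }


def gldm_features(D: np.ndarray) -> dict:
    s = _level_size_stats(D)
    return {
        "SmallDependenceEmphasis": s["small"],
        "LargeDependenceEmphasis": s["large"],
        "GrayLevelNonUniformity": s["gln"],
        "DependenceNonUniformity": s["sizen"],
        "DependenceNonUniformityNormalized": s["sizenn"],
        "GrayLevelVariance": s["glv"],
        "DependenceVariance": s["sizev"],
        "DependenceEntropy": s["entropy"],
        "LowGrayLevelEmphasis": s["lgl"],
        "HighGrayLevelEmphasis": s["hgl"],
        "SmallDependenceLowGrayLevelEmphasis": s["slgl"],
        "SmallDependenceHighGrayLevelEmphasis": s["shgl"],
        "LargeDependenceLowGrayLevelEmphasis": s["llgl"],
        "LargeDependenceHighGrayLevelEmphasis": s["lhgl"],
    }


# ----------------------------------------------------------------- NGTDM


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict:
    N = n_i.sum()
    if N == 0:
        return dict.fromkeys(
            ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"], 0.0
        )
    p_i = n_i / N
    lv = np.arange(1, len(n_i) + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())
    ps, ss, ls = p_i[present], s_i[present], lv[present]

    coars_den = (ps * ss).sum()
    coarseness = min(1.0 / coars_den, 1e6) if coars_den > 0 else 1e6

    if ngp > 1:
        dmat = (ls[:, None] - ls[None, :]) ** 2
        contrast = (
            (ps[:, None] * ps[None, :] * dmat).sum() / (ngp * (ngp - 1))
        ) * (ss.sum() / N)
        busy_den = np.abs(ls[:, None] * ps[:, None] - ls[None, :] * ps[None, :]).sum()
        busyness = coars_den / busy_den if busy_den > 0 else 0.0
        pi_si = ps * ss
        complexity = (
            np.abs(ls[:, None] - ls[None, :])
            * (pi_si[:, None] + pi_si[None, :])
            / (ps[:, None] + ps[None, :])
        ).sum() / N
        s_sum = ss.sum()
        strength = (
            ((ps[:, None] + ps[None, :]) * dmat).sum() / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }
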