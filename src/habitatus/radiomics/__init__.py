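"""Radiomics feature extraction: 927 named features per (image, region).

Per band (the original image plus eight wavelet bands) the extractor
computes 103 features: 10 shape, 18 first-order, 24 GLCM, 14 GLDM,
16 GLRLM, 16 GLSZM and 5 NGTDM. Shape depends only on the mask and is
included on every band, which is exactly the accounting that yields
927 = 103 + 8 x 103 (824 wavelet features). Feature names follow the
grammar ``{band}_{class}_{feature}``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..dataio import PairedCase
from ._features import (
    firstorder_features,
    gldm_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    shape_features,
)
from ._matrices import (
    gldm_matrix,
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngtdm_table,
    quantize,
)
from ._wavelet import BAND_NAMES, wavelet_bands

__all__ = [
    "extract_features",
    "per_habitat_features",
    "whole_lesion_features",
    "feature_name_counts",
    "EXPECTED_TOTAL",
    "EXPECTED_CLASS_COUNTS",
]

EXPECTED_CLASS_COUNTS = {
    "shape": 10,
    "firstorder": 18,
    "glcm": 24,
    "gldm": 14,
    "glrlm": 16,
    "glszm": 16,
    "ngtdm": 5,
}
EXPECTED_TOTAL = 927  # 103 original + 824 wavelet
MIN_REGION_PIXELS = 16


def _band_features(img: np.ndarray, mask: np.ndarray, bins: int) -> dict:
    vals = img[mask]
    q = quantize(img, mask, bins)
    out = {}
    out.update({f"firstorder_{k}": v for k, v in firstorder_features(vals, bins).items()})
    out.update({f"glcm_{k}": v for k, v in glcm_features(glcm_matrix(q, mask, bins)).items()})
    out.update({f"gldm_{k}": v for k, v in gldm_features(gldm_matrix(q, mask, bins)).items()})
    out.update({f"glrlm_{k}": v for k, v in glrlm_features(glrlm_matrix(q, mask, bins)).items()})
    out.update(
        {
            f"glszm_{k}": v
            for k, v in glszm_features(glszm_matrix(q, mask, bins), int(mask.sum())).items()
        }
    )
    out.update({f"ngtdm_{k}": v for k, v in ngtdm_features(*ngtdm_table(q, mask, bins)).items()})
    return out


def extract_features(
    image: np.ndarray,
    region_mask: np.ndarray,
    bin_count: int = 32,
    wavelet: str = "coif1",
    min_pixels: int = MIN_REGION_PIXELS,
    shape_on_wavelet: bool = True,
) -> pd.Series:
    """Extract the full 927-feature vector for one (image, region) pair.

    ``shape_on_wavelet`` keeps mask-only shape features on every wavelet
    band; disabling it yields 103 + 8*93 features instead and breaks the
    927 contract (exposed for ablation only).
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(region_mask) > 0
    if image.shape != mask.shape:
        raise ValueError("image and region mask shapes differ")
    n_px = int(mask.sum())
    if n_px < min_pixels:
        raise ValueError(f"region has {n_px} px, below the minimum of {min_pixels}")

    # crop to the region bounding box (with margin for filters)
    rows, cols = np.nonzero(mask)
    pad = 4
    r0, r1 = max(rows.min() - pad, 0), min(rows.max() + pad + 1, image.shape[0])
    c0, c1 = max(cols.min() - pad, 0), min(cols.max() + pad + 1, image.shape[1])
    img, m = image[r0:r1, c0:c1], mask[r0:r1, c0:c1]

    shape = {f"shape_{k}": v for k, v in shape_features(m).items()}
    out = {}
    out.update({f"original_{k}": v for k, v in shape.items()})
    out.update({f"original_{k}": v for k, v in _band_features(img, m, bin_count).items()})
    for band, bimg in wavelet_bands(img, wavelet).items():
        if shape_on_wavelet:
            out.update({f"{band}_{k}": v for k, v in shape.items()})
        out.update({f"{band}_{k}": v for k, v in _band_features(bimg, m, bin_count).items()})
    s = pd.Series(out, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        bad = s.index[~np.isfinite(s.to_numpy())].tolist()[:5]
        raise AssertionError(f"non-finite features produced: {bad}")
    return s


def feature_name_counts(names) -> dict:
    """Per-class counts on the original band plus the wavelet total."""
    counts = {cls: 0 for cls in EXPECTED_CLASS_COUNTS}
    wavelet_total = 0
    for name in names:
        band, cls, _ = name.split("_", 2)
        if band == "original":
            counts[cls] += 1
        else:
            wavelet_total += 1
    counts["wavelet"] = wavelet_total
    return counts


def whole_lesion_features(
    case: PairedCase,
    bin_count: int = 32,
    wavelet: str = "coif1",
    modalities: tuple = ("BMUS", "SWE"),
) -> pd.Series:
    """Whole-ROI ("omics") features: 927 per modality."""
    parts = []
    for mod, img in (("BMUS", case.bmus), ("SWE", case.swe)):
        if mod not in modalities:
            continue
        feats = extract_features(img, case.roi, bin_count, wavelet)
        feats.index = [f"{mod}_omics_{n}" for n in feats.index]
        parts.append(feats)
    row = pd.concat(parts)
    row.name = case.case_id
    return row


def per_habitat_features(
    case: PairedCase,
    bmus_habitats,
    swe_habitats,
    bin_count: int = 32,
    wavelet: str = "coif1",
    min_pixels: int = MIN_REGION_PIXELS,
) -> tuple[pd.Series, list[str]]:
    """Fused per-habitat feature row: 927 features per habitat slot.

    With the default cohort-level habitat counts (4 BMUS + 5 SWE) the row
    has 927 x 9 = 8343 columns. A habitat slot that is absent or smaller
    than ``min_pixels`` is zero-imputed; the returned list names the
    imputed slots so provenance can be recorded. Passing ``None`` for one
    modality's habitats restricts the row to the other modality.
    """
    template = None
    parts = []
    imputed = []
    for mod, img, hab in (
        ("BMUS", case.bmus, bmus_habitats),
        ("SWE", case.swe, swe_habitats),
    ):
        if hab is None:
            continue
        k = hab.selected_k
        for slot in range(1, k + 1):
            region = hab.label_map == slot
            prefix = f"{mod}_h{slot}"
            if int(region.sum()) >= min_pixels:
                feats = extract_features(img, region, bin_count, wavelet, min_pixels)
                if template is None:
                    template = feats.index
            else:
                imputed.append(prefix)
                if template is None:
                    # resolve the schema from the whole lesion once
                    template = extract_features(
                        img, case.roi, bin_count, wavelet
                    ).index
                feats = pd.Series(0.0, index=template)
            feats.index = [f"{prefix}_{n}" for n in feats.index]
            parts.append(feats)
    row = pd.concat(parts)
    row.name = case.case_id
    return row, imputed
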