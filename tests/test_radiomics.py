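"""The 927-feature extractor: count contracts, oracles, invariances."""

import numpy as np
import pandas as pd
import pytest

from habitatus.habitat.segment import HabitatResult
from habitatus.radiomics import (
    EXPECTED_CLASS_COUNTS,
    EXPECTED_TOTAL,
    extract_features,
    feature_name_counts,
    per_habitat_features,
    whole_lesion_features,
)


@pytest.fixture(scope="module")
def vector(one_case):
    return extract_features(one_case.bmus, one_case.roi)


def test_feature_count_contract(vector):
    assert len(vector) == EXPECTED_TOTAL
    counts = feature_name_counts(vector.index)
    for cls, n in EXPECTED_CLASS_COUNTS.items():
        assert counts[cls] == n, cls
    assert counts["wavelet"] == 824
    assert np.isfinite(vector.to_numpy()).all()


def test_feature_counts_hold_per_band(vector):
    bands = sorted({n.split("_", 1)[0] for n in vector.index})
    assert len(bands) == 9 and "original" in bands
    for band in bands:
        sub = [n for n in vector.index if n.startswith(band + "_")]
        assert len(sub) == 103


def test_constant_image_limits():
    mask = np.zeros((24, 24), bool)
    mask[4:20, 4:20] = True
    flat = extract_features(np.full((24, 24), 5.0), mask)
    assert flat["original_glcm_Contrast"] == 0.0
    assert flat["original_firstorder_Variance"] == 0.0
    # shape features depend only on the mask
    other = extract_features(np.full((24, 24), 42.0), mask)
    shape_cols = [n for n in flat.index if "_shape_" in n]
    assert (flat[shape_cols] == other[shape_cols]).all()


def test_firstorder_toy_region_matches_direct_computation():
    img = np.arange(1.0, 10.0).reshape(3, 3)
    pad = np.zeros((9, 9))
    pad[3:6, 3:6] = img
    mask = np.zeros((9, 9), bool)
    mask[3:6, 3:6] = True
    v = extract_features(pad, mask, min_pixels=4)
    x = img.ravel()
    assert v["original_firstorder_Mean"] == pytest.approx(5.0)
    assert v["original_firstorder_Maximum"] == 9.0
    assert v["original_firstorder_Minimum"] == 1.0
    assert v["original_firstorder_Median"] == 5.0
    assert v["original_firstorder_Energy"] == pytest.approx((x**2).sum())
    assert v["original_firstorder_Variance"] == pytest.approx(x.var())
    assert v["original_firstorder_Range"] == 8.0
    assert v["original_firstorder_RootMeanSquared"] == pytest.approx(
        np.sqrt((x**2).mean())
    )
    assert v["original_firstorder_MeanAbsoluteDeviation"] == pytest.approx(
        np.abs(x - 5.0).mean()
    )
    assert v["original_firstorder_Skewness"] == pytest.approx(0.0, abs=1e-12)


def test_shape_features_repeat_across_wavelet_bands(vector):
    shape_names = sorted(
        n.split("_", 1)[1] for n in vector.index
        if n.startswith("original_shape_")
    )
    for band in ("wavelet-LLL", "wavelet-HHL", "wavelet-LHH"):
        for sn in shape_names:
            assert vector[f"{band}_{sn}"] == vector[f"original_{sn}"]


def test_glcm_invariant_to_affine_intensity_rescaling(one_case):
    a = extract_features(one_case.bmus, one_case.roi)
    b = extract_features(one_case.bmus * 3.0 + 17.0, one_case.roi)
    glcm_cols = [n for n in a.index if n.startswith("original_glcm_")]
    assert np.allclose(a[glcm_cols], b[glcm_cols], rtol=1e-9)


def test_region_too_small_raises(one_case):
    tiny = np.zeros_like(one_case.roi)
    tiny[0:2, 0:3] = True
    with pytest.raises(ValueError, match="below the minimum"):
        extract_features(one_case.bmus, tiny)


def _fixed_k_maps(case, k_bmus=4, k_swe=5):
    from habitatus.habitat import pixel_features, segment_habitats

    out = {}
    for mod, img, k in (("BMUS", case.bmus, k_bmus), ("SWE", case.swe, k_swe)):
        stack = pixel_features(img, case.roi)
        rr, cc = stack.pixel_index.T
        out[mod] = segment_habitats(
            stack, fixed_k=k, seed=0, intensity=img[rr, cc],
            image_shape=img.shape, modality=mod,
        )
    return out


def test_fused_habitat_row_width_and_determinism(one_case):
    maps = _fixed_k_maps(one_case)
    row1, imp1 = per_habitat_features(one_case, maps["BMUS"], maps["SWE"])
    row2, _ = per_habitat_features(one_case, maps["BMUS"], maps["SWE"])
    assert len(row1) == EXPECTED_TOTAL * 9  # 4 BMUS + 5 SWE habitat slots
    assert not imp1
    assert row1.equals(row2)


def test_missing_habitat_slot_is_imputed_and_flagged(one_case):
    maps = _fixed_k_maps(one_case)
    swe = maps["SWE"]
    # empty the highest-stiffness slot
    lm = swe.label_map.copy()
    lm[lm == 5] = 4
    crippled = HabitatResult(lm, 5, swe.quality_curve, swe.modality)
    row, imputed = per_habitat_features(one_case, maps["BMUS"], crippled)
    assert len(row) == EXPECTED_TOTAL * 9
    assert imputed == ["SWE_h5"]
    assert (row.filter(like="SWE_h5_") == 0.0).all()


def test_whole_lesion_vs_habitat_table_widths(one_case):
    row = whole_lesion_features(one_case)
    assert len(row) == 2 * EXPECTED_TOTAL
    bmus_only = whole_lesion_features(one_case, modalities=("BMUS",))
    assert len(bmus_only) == EXPECTED_TOTAL


def test_single_habitat_vector_equals_whole_roi(one_case):
    lm = np.where(one_case.roi, 1, 0)
    single = HabitatResult(lm, 1, [], "SWE")
    row, _ = per_habitat_features(one_case, None, single)
    whole = extract_features(one_case.swe, one_case.roi)
    got = row.filter(like="SWE_h1_").to_numpy()
    assert np.allclose(got, whole.to_numpy(), rtol=1e-12)
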