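"""Manifest I/O, ROI transfer and the stratified cohort split."""

import numpy as np
import pandas as pd
import pytest

from habitatus.dataio import (
    PairedCase,
    load_manifest,
    split_cohort,
    transfer_roi,
)
from habitatus.synthdata import write_cohort


def _mask(shape=(20, 20)):
    m = np.zeros(shape, bool)
    m[5:15, 5:15] = True
    return m


def test_transfer_roi_identity_and_definition():
    m = _mask()
    assert (transfer_roi(m, (0, 0)) == m).all()
    single = np.zeros((30, 30), bool)
    single[10, 10] = True
    out = transfer_roi(single, (5, -3))
    assert out[15, 7] and out.sum() == 1


@pytest.mark.parametrize("shift", [(1, 1), (-3, 2), (4, -4), (0, 3)])
def test_transfer_roi_conserves_and_inverts(shift):
    m = _mask()
    out = transfer_roi(m, shift)
    assert out.sum() == m.sum()
    back = transfer_roi(out, (-shift[0], -shift[1]))
    assert (back == m).all()


def test_transfer_roi_out_of_bounds():
    with pytest.raises(ValueError, match="bounds"):
        transfer_roi(_mask(), (10, 0))


def test_split_reproduces_reference_cohort_sizes():
    # 206 cases (141 low / 65 high burden) at 80:20 -> 164 train / 42 test
    labels = np.array([0] * 141 + [1] * 65)
    ids = [f"p{i}" for i in range(206)]
    split = split_cohort(ids, labels, ratio=0.8, seed=10000)
    assert len(split.train_ids) == 164
    assert len(split.test_ids) == 42
    assert set(split.train_ids) | set(split.test_ids) == set(ids)


def test_split_small_cohort_and_determinism():
    ids = list("abcdefghij")
    labels = [0, 1] * 5
    s1 = split_cohort(ids, labels, ratio=0.8, seed=3)
    s2 = split_cohort(ids, labels, ratio=0.8, seed=3)
    assert s1 == s2
    assert len(s1.train_ids) == 8 and len(s1.test_ids) == 2


def test_split_stratification_within_one_case():
    rng = np.random.default_rng(0)
    labels = (rng.random(120) < 0.3).astype(int)
    ids = [f"c{i}" for i in range(120)]
    split = split_cohort(ids, labels, ratio=0.8, seed=1)
    lab = dict(zip(ids, labels))
    for cls in (0, 1):
        n_cls = sum(1 for v in lab.values() if v == cls)
        n_test = sum(1 for i in split.test_ids if lab[i] == cls)
        assert abs(n_test - 0.2 * n_cls) <= 1.0


def test_split_rejects_tiny_label_class():
    with pytest.raises(ValueError, match="fewer than 2"):
        split_cohort(list("abcdef"), [0, 0, 0, 0, 0, 1], ratio=0.8, seed=0)


def test_paired_case_validation():
    img = np.zeros((20, 20))
    with pytest.raises(ValueError, match="empty ROI"):
        PairedCase("x", img, img, np.zeros((20, 20)), {}, 0)
    small = np.zeros((20, 20))
    small[0, :5] = 1
    with pytest.raises(ValueError, match="minimum"):
        PairedCase("x", img, img, small, {}, 0)
    with pytest.raises(ValueError, match="mismatch"):
        PairedCase("x", img, np.zeros((10, 10)), _mask(), {}, 0)


def test_manifest_round_trip(small_cohort, tmp_path):
    manifest = write_cohort(small_cohort[:3], tmp_path)
    df = pd.read_csv(manifest)
    assert len(df) == 3
    required = {
        "case_id", "bmus_path", "swe_path", "mask_path",
        "nodal_burden", "age", "max_size_mm", "cT", "us_ln_status",
    }
    assert required <= set(df.columns)
    # 3 files per case: bmus, swe, mask
    assert sum(1 for c in df.columns if c.endswith("_path")) == 3
    cases = load_manifest(manifest)
    for (orig, _), loaded in zip(small_cohort[:3], cases):
        assert np.array_equal(orig.bmus, loaded.bmus)
        assert np.array_equal(orig.swe, loaded.swe)
        assert np.array_equal(orig.roi, loaded.roi)
        assert orig.label == loaded.label


def test_manifest_missing_file_is_named(small_cohort, tmp_path):
    manifest = write_cohort(small_cohort[:3], tmp_path)
    df = pd.read_csv(manifest)
    df.loc[0, "bmus_path"] = "absent.nii.gz"
    bad = tmp_path / "bad.csv"
    df.to_csv(bad, index=False)
    with pytest.raises(FileNotFoundError, match="absent.nii.gz"):
        load_manifest(bad)


def test_manifest_rejects_non_binary_mask(small_cohort, tmp_path):
    import nibabel as nib

    manifest = write_cohort(small_cohort[:3], tmp_path)
    df = pd.read_csv(manifest)
    bad_mask = np.zeros((96, 96), np.float32)
    bad_mask[10:40, 10:40] = 3.0
    bad_mask[20:30, 20:30] = 7.0
    nib.save(nib.Nifti1Image(bad_mask, np.eye(4)), tmp_path / df.loc[0, "mask_path"])
    with pytest.raises(ValueError, match="not binary"):
        load_manifest(manifest)
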