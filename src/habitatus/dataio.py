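"""Case I/O: manifests, ROI transfer between modalities, cohort splitting.

A case pairs a B-mode ultrasound (BMUS) image with the co-registered
shear-wave elastography (SWE) stiffness image of the same lesion. The
lesion ROI is drawn once on the BMUS frame; on dual-screen acquisitions
the SWE panel shows the same anatomy at a fixed XY offset, so the mask is
transferred by pure translation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

MIN_ROI_PIXELS = 32  # smallest ROI on which windowed texture stats are defined

MANIFEST_REQUIRED = {
    "case_id",
    "bmus_path",
    "swe_path",
    "mask_path",
    "nodal_burden",
    "age",
    "max_size_mm",
    "cT",
    "us_ln_status",
}


@dataclass
class PairedCase:
    """One lesion: BMUS + SWE images, ROI mask, covariates, burden label."""

    case_id: str
    bmus: np.ndarray
    swe: np.ndarray
    roi: np.ndarray
    covariates: dict = field(default_factory=dict)
    label: int = 0

    def __post_init__(self):
        self.bmus = np.asarray(self.bmus, dtype=float)
        self.swe = np.asarray(self.swe, dtype=float)
        self.roi = np.asarray(self.roi) > 0
        if self.bmus.ndim != 2 or self.swe.ndim != 2 or self.roi.ndim != 2:
            raise ValueError(f"case {self.case_id}: images must be 2-D")
        if self.bmus.shape != self.roi.shape or self.swe.shape != self.roi.shape:
            raise ValueError(
                f"case {self.case_id}: shape mismatch "
                f"bmus={self.bmus.shape} swe={self.swe.shape} roi={self.roi.shape}"
            )
        n_fg = int(self.roi.sum())
        if n_fg == 0:
            raise ValueError(f"case {self.case_id}: empty ROI mask")
        if n_fg < MIN_ROI_PIXELS:
            raise ValueError(
                f"case {self.case_id}: ROI has {n_fg} px, "
                f"minimum is {MIN_ROI_PIXELS}"
            )
        self.label = int(self.label)


@dataclass(frozen=True)
class CohortSplit:
    """A stratified train/test partition of case ids."""

    train_ids: tuple
    test_ids: tuple
    seed: int
    ratio: float

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test ids overlap: {sorted(overlap)[:5]}")


def _read_image(path: Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"referenced file does not exist: {path}")
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        return np.asarray(nib.load(str(path)).get_fdata(), dtype=float).squeeze()
    return np.asarray(iio.imread(path), dtype=float)


def _write_image(arr: np.ndarray, path: Path) -> None:
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine=np.eye(4))
        nib.save(img, str(path))
    else:
        a = np.asarray(arr)
        if a.dtype.kind == "f":
            a = a.astype(np.float32)
            # PNG cannot hold floats losslessly; scale to 16-bit
            lo, hi = a.min(), a.max()
            a = ((a - lo) / (hi - lo or 1.0) * 65535).round().astype(np.uint16)
        iio.imwrite(path, a)


def load_manifest(path) -> list[PairedCase]:
    """Read a cohort manifest CSV and all referenced images.

    Paths in the manifest are resolved relative to the manifest's
    directory. Images come back as float arrays; masks are binarized at
    >0 and validated (non-empty, within bounds, matching shapes).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = MANIFEST_REQUIRED - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing required columns: {sorted(missing)}")
    root = path.parent
    cases = []
    covar_cols = [
        c
        for c in df.columns
        if c not in ("case_id", "bmus_path", "swe_path", "mask_path", "nodal_burden")
    ]
    for _, row in df.iterrows():
        bmus = _read_image(root / row["bmus_path"])
        swe = _read_image(root / row["swe_path"])
        mask = _read_image(root / row["mask_path"])
        uniq = np.unique(mask)
        if len(uniq) > 2 or (len(uniq) == 2 and uniq[0] != 0):
            raise ValueError(
                f"case {row['case_id']}: mask {row['mask_path']} is not binary "
                f"(values {uniq[:6]})"
            )
        cases.append(
            PairedCase(
                case_id=str(row["case_id"]),
                bmus=bmus,
                swe=swe,
                roi=mask > 0,
                covariates={c: row[c] for c in covar_cols},
                label=int(row["nodal_burden"]),
            )
        )
    return cases


def transfer_roi(roi: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Translate a binary mask by (drow, dcol) pixels.

    Transfers the BMUS-drawn lesion mask onto the SWE panel of a
    dual-screen frame. Every foreground pixel must stay inside the image;
    foreground count is preserved exactly.
    """
    roi = np.asarray(roi) > 0
    dr, dc = int(shift[0]), int(shift[1])
    rows, cols = np.nonzero(roi)
    if rows.size == 0:
        raise ValueError("cannot transfer an empty mask")
    nr, nc = rows + dr, cols + dc
    h, w = roi.shape
    if nr.min() < 0 or nc.min() < 0 or nr.max() >= h or nc.max() >= w:
        raise ValueError(
            f"shift ({dr},{dc}) pushes the ROI out of the {h}x{w} image bounds"
        )
    out = np.zeros_like(roi)
    out[nr, nc] = True
    return out


def split_cohort(ids, labels, ratio: float = 0.8, seed: int = 10000) -> CohortSplit:
    """Stratified train/test split of case ids.

    The test cohort holds ceil((1-ratio) * n) cases, apportioned across
    label classes by largest remainder so each class's test fraction stays
    within one case of the target. 206 cases at 80:20 give 164/42.
    """
    ids = list(ids)
    labels = np.asarray(labels).astype(int)
    n = len(ids)
    if n != len(labels):
        raise ValueError("ids and labels must have equal length")
    if n < 5:
        raise ValueError("need at least 5 cases to split")
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        small = classes[counts < 2]
        raise ValueError(f"label class {small} has fewer than 2 members")
    n_test = math.ceil((1.0 - ratio) * n)
    # largest-remainder apportionment of the test quota over classes
    quota = counts * (1.0 - ratio)
    base = np.floor(quota).astype(int)
    rem = n_test - base.sum()
    order = np.argsort(-(quota - base))
    alloc = base.copy()
    for j in order[: max(rem, 0)]:
        alloc[j] += 1
    rng = np.random.default_rng(seed)
    test_ids, train_ids = [], []
    for cls, k in zip(classes, alloc):
        members = [i for i, l in zip(ids, labels) if l == cls]
        perm = rng.permutation(len(members))
        chosen = {members[p] for p in perm[:k]}
        test_ids.extend(m for m in members if m in chosen)
        train_ids.extend(m for m in members if m not in chosen)
    return CohortSplit(
        train_ids=tuple(train_ids), test_ids=tuple(test_ids), seed=seed, ratio=ratio
    )
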