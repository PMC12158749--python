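"""Synthetic paired-ultrasound cohort generator.

Emulates the data regime of a bi-modal breast-ultrasound habitat study:
each lesion is an ellipse containing a small number of spatially
contiguous subregions ("habitats") that differ in B-mode texture and in
shear-wave stiffness. BMUS images carry multiplicative Rayleigh-like
speckle; SWE images are scalar stiffness fields on a 0-180 kPa display
scale with a smooth spatial drift. A clinical covariate table is drawn so
that clinical T stage and ultrasound-reported lymph-node status raise the
odds of high nodal burden while the remaining covariates are independent
of it -- the association pattern a univariate screen should find.

High-burden lesions additionally get larger between-habitat stiffness
contrast (with the lesion-mean stiffness held fixed) and a habitat count
drawn from the upper part of the configured range, planting an
image-level signal that lives in intratumoral heterogeneity rather than
in any whole-lesion mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .dataio import PairedCase, _write_image

SWE_MAX_KPA = 180.0  # display-scale ceiling of the stiffness map

# covariate marginals (probability of the second level / of "positive")
COVARIATE_MARGINALS = {
    "cT2": 0.515,
    "us_ln_positive": 0.306,
    "histology_other": 0.054,
    "grade_high": 0.272,
    "er_positive": 0.777,
    "pr_positive": 0.704,
    "her2_positive": 0.335,
    "ki67_high": 0.519,
}
MOLECULAR_SUBTYPES = ("LuminalA", "LuminalB", "HER2", "TripleNegative")
SUBTYPE_PROBS = (0.228, 0.553, 0.083, 0.136)

# log odds-ratios of high burden for the two genuinely associated covariates
BETA_CT2 = 0.75
BETA_USLN = 1.0


@dataclass(frozen=True)
class SynthConfig:
    n_cases: int = 60
    habitat_count_range: tuple[int, int] = (2, 5)
    image_size: tuple[int, int] = (128, 128)
    lesion_axes_range: tuple[int, int] = (18, 36)
    speckle_sigma: float = 0.25
    swe_smoothness: float = 4.0
    stiffness_contrast: float = 40.0
    resolution_blur: float = 2.0
    high_burden_fraction: float = 0.316
    burden_contrast_boost: float = 0.6
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.habitat_count_range
        if not (1 <= lo <= hi <= 5):
            raise ValueError("habitat_count_range must lie within [1, 5]")
        if not 0 < self.high_burden_fraction < 1:
            raise ValueError("high_burden_fraction must be in (0, 1)")
        h, w = self.image_size
        margin = 3  # keep surrounding tissue around the lesion
        if self.lesion_axes_range[1] * 2 + 2 * margin > min(h, w):
            raise ValueError(
                f"lesion (max axis {self.lesion_axes_range[1]}) does not fit a "
                f"{h}x{w} image with a {margin}-px margin"
            )


@dataclass
class GroundTruth:
    """Planted truth for one synthetic case."""

    habitat_map: np.ndarray  # 0 background, 1..K inside the lesion
    nodal_burden: int
    covariates: dict = field(default_factory=dict)


def _lesion_ellipse(rng, cfg) -> tuple[np.ndarray, tuple]:
    h, w = cfg.image_size
    lo, hi = cfg.lesion_axes_range
    a = rng.uniform(lo, hi)
    b = rng.uniform(lo, hi)
    theta = rng.uniform(0, np.pi)
    margin = 3
    r = max(a, b)
    cy = rng.uniform(r + margin, h - r - margin)
    cx = rng.uniform(r + margin, w - r - margin)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask, (cy, cx, a, b, theta)


def _voronoi_habitats(rng, mask: np.ndarray, k: int) -> np.ndarray:
    """Partition the lesion into k contiguous cells from random interior seeds.

    Seed draws are rejected until every cell holds at least half the
    average cell size, so no habitat degenerates into a sliver.
    """
    rows, cols = np.nonzero(mask)
    labels = np.zeros(mask.shape, dtype=int)
    if k == 1:
        labels[mask] = 1
        return labels
    min_size = max(8, rows.size // (2 * k))
    for _ in range(200):
        pick = rng.choice(rows.size, size=k, replace=False)
        seeds = np.stack([rows[pick], cols[pick]], axis=1).astype(float)
        d2 = (rows[:, None] - seeds[None, :, 0]) ** 2 + (
            cols[:, None] - seeds[None, :, 1]
        ) ** 2
        assign = d2.argmin(axis=1)
        if (
            len(np.unique(assign)) == k
            and np.bincount(assign, minlength=k).min() >= min_size
        ):
            labels[rows, cols] = assign + 1
            return labels
    # fall back to however many non-empty cells the last draw produced
    _, assign = np.unique(assign, return_inverse=True)
    labels[rows, cols] = assign + 1
    return labels


def _correlated_noise(rng, shape, sigma) -> np.ndarray:
    """Unit-variance Gaussian field with correlation length ~sigma pixels."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _habitat_field(habitat_map, values, background, blur) -> np.ndarray:
    """Piecewise-constant per-habitat map softened by a resolution blur."""
    out = np.full(habitat_map.shape, float(background))
    for lab in range(1, habitat_map.max() + 1):
        out[habitat_map == lab] = values[lab - 1]
    return gaussian_filter(out, blur) if blur > 0 else out


def _bmus_image(rng, cfg, habitat_map, mask) -> np.ndarray:
    h, w = cfg.image_size
    k = max(int(habitat_map.max()), 1)
    # habitat identity on two texture axes: echogenicity (mean level) and
    # speckle-pattern grain (correlation length); equal texture strength
    # keeps per-habitat feature spreads comparable
    means = 70.0 + 50.0 * rng.permutation(np.linspace(0, 1, k))
    corr = 0.6 + 2.4 * rng.permutation(np.linspace(0, 1, k))
    img = _habitat_field(habitat_map, means, 40.0, cfg.resolution_blur)
    weights = np.stack(
        [
            gaussian_filter((habitat_map == lab).astype(float), cfg.resolution_blur)
            for lab in range(1, k + 1)
        ]
    )
    tex = sum(
        weights[lab - 1] * 18.0 * _correlated_noise(rng, (h, w), corr[lab - 1])
        for lab in range(1, k + 1)
    )
    img = img + tex + 8.0 * (1 - weights.sum(axis=0)) * _correlated_noise(
        rng, (h, w), 1.2
    )
    if cfg.speckle_sigma > 0:
        ray = rng.rayleigh(scale=1.0, size=(h, w))
        ray = ray / np.sqrt(np.pi / 2)  # unit mean
        speckle = 1.0 + cfg.speckle_sigma * (ray - 1.0)
        img = img * np.clip(speckle, 0.05, None)
    return np.clip(img, 0.0, None)


def _swe_image(rng, cfg, habitat_map, mask, burden) -> np.ndarray:
    """Scalar stiffness image with a subregion-localised burden effect.

    The lesion's total stiffness spread is set by ``stiffness_contrast``
    and does not depend on burden. High burden changes the character of
    the *stiffest* habitat only (its fine-texture amplitude grows by
    ``burden_contrast_boost``): whole-lesion statistics see this diluted
    by the other habitats, while the per-habitat feature slot isolates
    it — the planted signal lives at the habitat level.
    """
    h, w = cfg.image_size
    k = max(int(habitat_map.max()), 1)
    base = rng.uniform(45.0, 75.0)  # lesion-mean stiffness, kPa-like
    # total lesion stiffness SD; bounded so habitat means stay on-scale
    total_sd = min(
        0.36 * cfg.stiffness_contrast,
        (base - 5.0) / 1.8,
        (SWE_MAX_KPA - 5.0 - base) / 1.8,
    )
    phi = 0.25  # within-habitat (fine texture) share of the variance
    if k == 1:
        means = np.array([base])
        amps = np.array([1.0])  # homogeneous lesion: fine grain only
    else:
        offsets = rng.permutation(np.linspace(-0.5, 0.5, k))
        offsets = offsets - offsets.mean()
        offsets = offsets / offsets.std()  # unit-SD spacing
        means = base + total_sd * np.sqrt(1.0 - phi) * offsets
        # habitat-specific texture strengths around the within-variance budget
        spread = rng.permutation(np.geomspace(1 / 2.2, 2.2, k))
        amps = total_sd * np.sqrt(phi) * spread / np.sqrt((spread**2).mean())
        if burden:
            amps = amps.copy()
            amps[int(np.argmax(means))] *= 1.0 + cfg.burden_contrast_boost
    meanmap = _habitat_field(habitat_map, means, rng.uniform(8.0, 20.0),
                             cfg.resolution_blur)
    ampmap = _habitat_field(habitat_map, amps, 0.5, cfg.resolution_blur)
    img = meanmap + ampmap * rng.standard_normal((h, w))
    img = img + 1.0 * _correlated_noise(rng, (h, w), cfg.swe_smoothness)
    return np.clip(img, 0.0, SWE_MAX_KPA)


def _draw_covariates(rng) -> dict:
    m = COVARIATE_MARGINALS
    return {
        "age": float(np.round(rng.normal(51.6, 10.3), 1)),
        "max_size_mm": float(np.round(np.clip(rng.normal(21.5, 7.5), 5, 50), 1)),
        "cT": 2 if rng.random() < m["cT2"] else 1,
        "histology": "other" if rng.random() < m["histology_other"] else "ductal",
        "grade": "high" if rng.random() < m["grade_high"] else "low_intermediate",
        "er_status": int(rng.random() < m["er_positive"]),
        "pr_status": int(rng.random() < m["pr_positive"]),
        "her2_status": int(rng.random() < m["her2_positive"]),
        "ki67_status": int(rng.random() < m["ki67_high"]),
        "molecular_subtype": MOLECULAR_SUBTYPES[
            rng.choice(len(MOLECULAR_SUBTYPES), p=SUBTYPE_PROBS)
        ],
        "us_ln_status": int(rng.random() < m["us_ln_positive"]),
    }


def _calibrate_intercept(lin: np.ndarray, target: float) -> float:
    """Intercept b0 such that mean sigmoid(b0 + lin) equals the target rate."""
    lo, hi = -10.0, 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        p = 1.0 / (1.0 + np.exp(-(mid + lin)))
        if p.mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def draw_clinical_cohort(
    n_cases: int, high_burden_fraction: float, rng
) -> tuple[list[dict], np.ndarray]:
    """Draw covariates and nodal-burden labels for n cases.

    Burden follows a logistic model in which only cT stage 2 and
    US-reported positive nodes raise the odds; the intercept is
    calibrated so the expected high-burden rate matches the target.
    Returns (covariate dicts, burden array).
    """
    covs = [_draw_covariates(rng) for _ in range(n_cases)]
    lin = np.array(
        [
            BETA_CT2 * (c["cT"] == 2) + BETA_USLN * c["us_ln_status"]
            for c in covs
        ],
        dtype=float,
    )
    b0 = _calibrate_intercept(lin, high_burden_fraction)
    burden = (
        rng.random(n_cases) < 1.0 / (1.0 + np.exp(-(b0 + lin)))
    ).astype(int)
    return covs, burden


def generate_cohort(config: SynthConfig) -> list[tuple[PairedCase, GroundTruth]]:
    """Generate a deterministic synthetic cohort.

    Covariates are drawn first; nodal burden follows a logistic model in
    which only cT stage 2 and US-reported positive nodes raise the odds
    (intercept calibrated so the cohort's high-burden rate matches
    ``high_burden_fraction``); images are then rendered conditional on
    the burden via the heterogeneity coupling described in the module
    docstring. Identical config (including seed) gives a bit-identical
    cohort.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    covs, burden = draw_clinical_cohort(cfg.n_cases, cfg.high_burden_fraction, rng)

    lo_k, hi_k = cfg.habitat_count_range
    out = []
    for i in range(cfg.n_cases):
        mask, _ = _lesion_ellipse(rng, cfg)
        if burden[i] and hi_k > lo_k:
            k = int(rng.integers((lo_k + hi_k + 1) // 2, hi_k + 1))
        else:
            k = int(rng.integers(lo_k, hi_k + 1))
        habitat_map = _voronoi_habitats(rng, mask, k)
        bmus = _bmus_image(rng, cfg, habitat_map, mask)
        swe = _swe_image(rng, cfg, habitat_map, mask, int(burden[i]))
        # store float32-representable values so file round-trips are exact
        case = PairedCase(
            case_id=f"case{i:04d}",
            bmus=bmus.astype(np.float32),
            swe=swe.astype(np.float32),
            roi=mask,
            covariates=dict(covs[i]),
            label=int(burden[i]),
        )
        out.append(
            (case, GroundTruth(habitat_map, int(burden[i]), dict(covs[i])))
        )
    return out


def write_cohort(cohort, directory) -> Path:
    """Write images/masks as NIfTI plus a one-row-per-case CSV manifest.

    Returns the manifest path. The manifest stores file paths relative to
    its own directory so the cohort is relocatable; it round-trips
    through :func:`habitatus.dataio.load_manifest` losslessly (float32).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for case, truth in cohort:
        cid = case.case_id
        names = {
            "bmus_path": f"{cid}_bmus.nii.gz",
            "swe_path": f"{cid}_swe.nii.gz",
            "mask_path": f"{cid}_mask.nii.gz",
        }
        try:
            _write_image(case.bmus.astype(np.float32), directory / names["bmus_path"])
            _write_image(case.swe.astype(np.float32), directory / names["swe_path"])
            _write_image(
                case.roi.astype(np.float32), directory / names["mask_path"]
            )
            _write_image(
                truth.habitat_map.astype(np.float32),
                directory / f"{cid}_habitats.nii.gz",
            )
        except OSError as exc:
            raise OSError(f"failed writing files for {cid} under {directory}: {exc}")
        rows.append(
            {"case_id": cid, **names, "nodal_burden": case.label, **case.covariates}
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
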