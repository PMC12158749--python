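"""End-to-end orchestration: data -> habitats -> features -> selection -> models.

A run is configured once, logged, and written to a run directory that
contains habitat maps, feature tables, the selection result, per-model
reports, the ranked comparison, ROC figures and the resolved config.
Re-running an identical config reproduces all numeric outputs: the global
seed fans out to per-stage seeds through stable offsets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import radiomics
from .dataio import PairedCase, load_manifest, split_cohort
from .habitat import pixel_features, segment_habitats
from .modeling import MODEL_NAMES, compare_models, roc_overlay, train_eval
from .selection import select_features
from .synthdata import SynthConfig, generate_cohort

log = logging.getLogger("habitatus")

# stable per-stage seed offsets derived from the global seed
_STAGE_OFFSETS = {"synth": 11, "split": 23, "habitat": 37, "selection": 53, "model": 71}


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 1000 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class RunConfig:
    manifest: str | None = None
    synth: SynthConfig | None = None
    split_seed: int = 10000
    test_fraction: float = 0.2
    k_bmus: int = 4
    k_swe: int = 5
    window: int = 7
    clustering_levels: int = 32
    bin_count: int = 32
    wavelet: str = "coif1"
    corr_threshold: float = 0.9
    cv_folds: int = 10
    feature_sets: tuple = ("BMUS_omics", "BMUS_habitat", "SWE_omics", "SWE_habitat")
    models: tuple = MODEL_NAMES
    bootstrap_n: int = 2000
    seed: int = 0
    out_dir: str = "run"

    def validate(self) -> None:
        if (self.manifest is None) == (self.synth is None):
            raise ValueError("configure exactly one of manifest or synth")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0,1)")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        for fs in self.feature_sets:
            mod, kind = fs.split("_")
            if mod not in ("BMUS", "SWE") or kind not in ("omics", "habitat"):
                raise ValueError(f"bad feature set {fs!r}")


def _needed_modalities(cfg, kind: str) -> tuple:
    return tuple(
        mod
        for mod in ("BMUS", "SWE")
        if f"{mod}_{kind}" in cfg.feature_sets
    )


def _habitat_maps(cases, cfg) -> dict:
    """Fixed-k habitat maps per case and modality (uniform table schema)."""
    seed = stage_seed(cfg.seed, "habitat")
    needed = _needed_modalities(cfg, "habitat")
    maps = {}
    for case in cases:
        per_case = {}
        for mod, img, k in (("BMUS", case.bmus, cfg.k_bmus), ("SWE", case.swe, cfg.k_swe)):
            if mod not in needed:
                continue
            stack = pixel_features(img, case.roi, cfg.window, cfg.clustering_levels)
            rr, cc = stack.pixel_index[:, 0], stack.pixel_index[:, 1]
            per_case[mod] = segment_habitats(
                stack,
                fixed_k=k,
                seed=seed,
                intensity=img[rr, cc],
                image_shape=img.shape,
                modality=mod,
            )
        maps[case.case_id] = per_case
        log.info("habitats: %s done", case.case_id)
    return maps


def build_tables(cases, cfg, habitat_maps=None) -> dict[str, pd.DataFrame]:
    """Assemble the four feature tables (modality x omics/habitat)."""
    need_habitat = any(fs.endswith("habitat") for fs in cfg.feature_sets)
    if need_habitat and habitat_maps is None:
        habitat_maps = _habitat_maps(cases, cfg)
    omics_mods = _needed_modalities(cfg, "omics")
    omics_rows, habitat_rows, imputed = [], [], {}
    for case in cases:
        if omics_mods:
            omics_rows.append(
                radiomics.whole_lesion_features(
                    case, cfg.bin_count, cfg.wavelet, modalities=omics_mods
                )
            )
        if need_habitat:
            row, imp = radiomics.per_habitat_features(
                case,
                habitat_maps[case.case_id].get("BMUS"),
                habitat_maps[case.case_id].get("SWE"),
                cfg.bin_count,
                cfg.wavelet,
            )
            habitat_rows.append(row)
            if imp:
                imputed[case.case_id] = imp
        log.info("features: %s done", case.case_id)
    tables = {}
    if omics_rows:
        omics = pd.DataFrame(omics_rows)
        for mod in ("BMUS", "SWE"):
            if f"{mod}_omics" in cfg.feature_sets:
                tables[f"{mod}_omics"] = omics.filter(regex=f"^{mod}_")
    if habitat_rows:
        hab = pd.DataFrame(habitat_rows)
        for mod in ("BMUS", "SWE"):
            if f"{mod}_habitat" in cfg.feature_sets:
                tables[f"{mod}_habitat"] = hab.filter(regex=f"^{mod}_")
    if imputed:
        log.warning("zero-imputed habitat slots: %s", imputed)
    tables["_imputed"] = imputed
    return tables


def run(config: RunConfig) -> Path:
    """Execute the full pipeline and return the run directory."""
    cfg = config
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    resolved = dataclasses.asdict(cfg)
    if cfg.synth is not None:
        resolved["synth"] = dataclasses.asdict(cfg.synth)
    (out / "config.json").write_text(json.dumps(resolved, indent=2, default=str))

    if cfg.synth is not None:
        cohort = generate_cohort(cfg.synth)
        cases = [c for c, _ in cohort]
    else:
        cases = load_manifest(cfg.manifest)
    ids = [c.case_id for c in cases]
    labels = np.array([c.label for c in cases])
    split = split_cohort(
        ids, labels, ratio=1 - cfg.test_fraction, seed=cfg.split_seed
    )

    habitat_maps = None
    if any(fs.endswith("habitat") for fs in cfg.feature_sets):
        habitat_maps = _habitat_maps(cases, cfg)
        hab_dir = out / "habitat_maps"
        hab_dir.mkdir(exist_ok=True)
        from .dataio import _write_image

        for cid, per_case in habitat_maps.items():
            for mod, res in per_case.items():
                _write_image(
                    res.label_map.astype(np.float32),
                    hab_dir / f"{cid}_{mod}_habitats.nii.gz",
                )
                (hab_dir / f"{cid}_{mod}_quality.json").write_text(
                    json.dumps(
                        [dataclasses.asdict(q) for q in res.quality_curve]
                    )
                )
    try:
        tables = build_tables(cases, cfg, habitat_maps)
    except Exception as exc:
        raise RuntimeError(f"feature stage failed: {exc}") from exc
    imputed = tables.pop("_imputed")
    (out / "imputed_slots.json").write_text(json.dumps(imputed, indent=2))

    label_of = dict(zip(ids, labels.tolist()))
    all_test_reports = {}
    summary_rows = []
    for fs_name, table in tables.items():
        table.to_csv(out / f"features_{fs_name}.csv")
        tr_rows = [cid for cid in table.index if cid in set(split.train_ids)]
        te_rows = [cid for cid in table.index if cid in set(split.test_ids)]
        y = np.array([label_of[c] for c in table.index])
        try:
            sel = select_features(
                table.loc[tr_rows],
                [label_of[c] for c in tr_rows],
                corr_threshold=cfg.corr_threshold,
                folds=cfg.cv_folds,
                seed=stage_seed(cfg.seed, "selection"),
            )
        except ValueError as exc:
            # an empty selection means this feature set carries no signal
            # at this cohort size; skip it rather than abort the run
            log.warning("selection failed for %s: %s", fs_name, exc)
            (out / f"selection_{fs_name}.json").write_text(
                json.dumps({"error": str(exc)}, indent=2)
            )
            continue
        (out / f"selection_{fs_name}.json").write_text(
            json.dumps(
                {
                    "kept_features": sel.kept_features,
                    "lasso_alpha": sel.lasso_alpha,
                    "n_dropped_by_correlation": len(sel.dropped_by_correlation),
                    "n_dropped_by_threshold": len(sel.dropped_by_threshold),
                },
                indent=2,
            )
        )
        sub = table[sel.kept_features]
        reports = []
        for name in cfg.models:
            tr_rep, te_rep = train_eval(
                sub,
                y,
                split,
                name,
                seed=stage_seed(cfg.seed, "model"),
                bootstrap_n=cfg.bootstrap_n,
            )
            reports.append(te_rep)
            summary_rows.append(
                {"feature_set": fs_name, "model": name, "cohort": "train", "auc": tr_rep.auc}
            )
            summary_rows.append(
                {"feature_set": fs_name, "model": name, "cohort": "test", "auc": te_rep.auc}
            )
        all_test_reports[fs_name] = reports
        compare_models(reports).to_csv(out / f"comparison_{fs_name}.csv", index=False)
    if all_test_reports:
        roc_overlay(all_test_reports, out / "roc_overlay.png")
        pd.DataFrame(summary_rows).to_csv(out / "auc_summary.csv", index=False)
    (out / "split.json").write_text(
        json.dumps({"train_ids": list(split.train_ids), "test_ids": list(split.test_ids)})
    )
    log.info("run complete: %s", out)
    return out
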