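"""Classifier benchmarking with the full diagnostic metric suite.

Eleven classifiers (LR, NaiveBayes, SVM, KNN, RandomForest, ExtraTrees,
XGBoost, LightGBM, GradientBoosting, AdaBoost, MLP) are trained on the
training cohort only and reported on both cohorts with AUC (stratified
bootstrap 95% CI), accuracy, sensitivity, specificity, PPV, NPV,
precision, recall and F1. The operating threshold maximises Youden's J
on the training ROC and is then frozen for the test cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

MODEL_NAMES = (
    "LR",
    "NaiveBayes",
    "SVM",
    "KNN",
    "RandomForest",
    "ExtraTrees",
    "XGBoost",
    "LightGBM",
    "GradientBoosting",
    "AdaBoost",
    "MLP",
)


def make_model(name: str, seed: int = 0):
    """Instantiate a named classifier with library-default hyperparameters."""
    if name == "LR":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        )
    if name == "NaiveBayes":
        return GaussianNB()
    if name == "SVM":
        return make_pipeline(
            StandardScaler(), SVC(probability=True, random_state=seed)
        )
    if name == "KNN":
        return make_pipeline(StandardScaler(), KNeighborsClassifier())
    if name == "RandomForest":
        return RandomForestClassifier(random_state=seed)
    if name == "ExtraTrees":
        return ExtraTreesClassifier(random_state=seed)
    if name == "XGBoost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, eval_metric="logloss", verbosity=0, n_jobs=1
        )
    if name == "LightGBM":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1)
    if name == "GradientBoosting":
        return GradientBoostingClassifier(random_state=seed)
    if name == "AdaBoost":
        return AdaBoostClassifier(random_state=seed)
    if name == "MLP":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(max_iter=1000, random_state=seed),
        )
    raise ValueError(f"unknown model name: {name!r} (choose from {MODEL_NAMES})")


@dataclass
class ModelReport:
    model_name: str
    cohort: str  # "train" or "test"
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    precision: float
    recall: float
    f1: float
    threshold: float
    roc_points: list = field(default_factory=list)


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def _bootstrap_auc_ci(
    y: np.ndarray, s: np.ndarray, n_boot: int, seed: int, level: float = 0.95
) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the AUC."""
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos, size=pos.size, replace=True),
                rng.choice(neg, size=neg.size, replace=True),
            ]
        )
        aucs[b] = roc_auc_score(y[idx], s[idx])
    lo, hi = np.percentile(aucs, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def _report(name, cohort, y, s, threshold, n_boot, seed) -> ModelReport:
    y = np.asarray(y).astype(int)
    auc = float(roc_auc_score(y, s))
    lo, hi = _bootstrap_auc_ci(y, s, n_boot, seed)
    lo, hi = min(lo, auc), max(hi, auc)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    f1 = 2 * ppv * sen / (ppv + sen) if ppv + sen else 0.0
    fpr, tpr, _ = roc_curve(y, s)
    return ModelReport(
        model_name=name,
        cohort=cohort,
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        accuracy=(tp + tn) / len(y),
        sensitivity=sen,
        specificity=spe,
        ppv=ppv,
        npv=npv,
        precision=ppv,
        recall=sen,
        f1=f1,
        threshold=float(threshold),
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
    )


def evaluate_fitted(
    model, X_train, y_train, X_test, y_test, model_name="model",
    bootstrap_n: int = 2000, seed: int = 0,
) -> tuple[ModelReport, ModelReport]:
    """Report a fitted model on both cohorts at the train-Youden threshold."""
    s_tr = _scores(model, X_train)
    s_te = _scores(model, X_test)
    fpr, tpr, thr = roc_curve(y_train, s_tr)
    i = int(np.argmax(tpr - fpr))
    # midpoint between adjacent score thresholds: robust when the optimal
    # cut sits exactly on an observed training score
    lo = thr[i + 1] if i + 1 < len(thr) else thr[i] - 1.0
    threshold = float((thr[i] + max(lo, thr[i] - 2.0)) / 2.0)
    return (
        _report(model_name, "train", y_train, s_tr, threshold, bootstrap_n, seed),
        _report(model_name, "test", y_test, s_te, threshold, bootstrap_n, seed),
    )


def train_eval(
    features,
    labels,
    split,
    model_name: str,
    seed: int = 0,
    bootstrap_n: int = 2000,
) -> tuple[ModelReport, ModelReport]:
    """Train one named classifier on the training cohort and report both.

    ``features`` is a DataFrame indexed by case id; ``split`` a
    :class:`habitatus.dataio.CohortSplit`.
    """
    y = np.asarray(labels).astype(int)
    if isinstance(features, pd.DataFrame):
        idx = {cid: i for i, cid in enumerate(features.index)}
        tr = np.array([idx[c] for c in split.train_ids])
        te = np.array([idx[c] for c in split.test_ids])
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        tr = np.asarray(split.train_ids, dtype=int)
        te = np.asarray(split.test_ids, dtype=int)
    if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
        raise ValueError("a cohort contains a single label class")
    model = make_model(model_name, seed)
    model.fit(X[tr], y[tr])
    return evaluate_fitted(
        model, X[tr], y[tr], X[te], y[te], model_name, bootstrap_n, seed
    )


def compare_models(reports: list[ModelReport]) -> pd.DataFrame:
    """Ranked AUC comparison of test-cohort reports.

    Reports must share a cohort; rows are sorted by descending AUC with
    ties broken by model name.
    """
    if not reports:
        raise ValueError("no reports to compare")
    cohorts = {r.cohort for r in reports}
    if len(cohorts) > 1:
        raise ValueError(f"reports mix cohorts: {sorted(cohorts)}")
    rows = [
        {
            "model": r.model_name,
            "auc": r.auc,
            "auc_ci_low": r.auc_ci_low,
            "auc_ci_high": r.auc_ci_high,
            "accuracy": r.accuracy,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
            "ppv": r.ppv,
            "npv": r.npv,
            "f1": r.f1,
        }
        for r in reports
    ]
    df = pd.DataFrame(rows).sort_values(
        ["auc", "model"], ascending=[False, True], kind="stable"
    )
    return df.reset_index(drop=True)


def roc_overlay(reports_by_set: dict, path) -> None:
    """Write a multi-panel ROC overlay figure (one panel per feature set)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(reports_by_set)
    ncols = min(n, 2)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(6 * ncols, 5 * nrows), squeeze=False)
    for ax, (name, reports) in zip(axes.ravel(), reports_by_set.items()):
        for r in sorted(reports, key=lambda r: -r.auc):
            pts = np.array(r.roc_points)
            ax.plot(pts[:, 0], pts[:, 1], label=f"{r.model_name} ({r.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_title(name)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(fontsize=7)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
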