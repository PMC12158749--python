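"""Feature selection: Pearson correlation filter then logistic LASSO.

Both steps see training rows only. The correlation filter greedily drops
the column most correlated with the remainder until no retained pair has
|r| > 0.9. LASSO is an L1-penalised logistic regression whose penalty is
chosen by 10-fold cross-validated deviance on a 100-point log-spaced
grid, with the one-standard-error rule (the sparsest penalty whose CV
deviance is within one SE of the minimum; plain CV-min selection is
notoriously permissive for feature screening and is available via
``rule="min"``). Surviving features are those with |coefficient| >= 1e-6
(smaller coefficients are treated as noise-driven and excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

COEF_THRESHOLD = 1e-6


@dataclass
class SelectionResult:
    kept_features: list
    lasso_alpha: float
    coefficients: dict
    dropped_by_correlation: list = field(default_factory=list)
    dropped_by_threshold: list = field(default_factory=list)
    coef_threshold: float = COEF_THRESHOLD
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None


def correlation_filter(
    table: pd.DataFrame, threshold: float = 0.9
) -> tuple[pd.DataFrame, list]:
    """Drop highly correlated columns; returns (filtered table, dropped names).

    Constant columns are dropped first (their correlation is undefined).
    Survivor rule: columns are prioritised by descending mean absolute
    correlation with all other columns; sweeping in that order, a column
    is dropped if it is still correlated above the threshold with any
    surviving column. Deterministic, and scales to radiomics-width tables
    (the pairwise matrix is streamed in column blocks, never fully
    materialised).
    """
    if table.shape[1] < 2:
        raise ValueError("correlation filter needs at least 2 columns")
    X = table.to_numpy(dtype=np.float64)
    sd = X.std(axis=0)
    dropped = [c for c, s in zip(table.columns, sd) if s == 0]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant column(s) before correlation "
            "filtering",
            stacklevel=2,
        )
        table = table.drop(columns=dropped)
        X = table.to_numpy(dtype=np.float64)
        sd = X.std(axis=0)
    n, m = X.shape
    Z = (X - X.mean(axis=0)) / sd
    # mean |r| per column, in blocks to bound memory
    mean_abs = np.empty(m)
    for lo in range(0, m, 1024):
        hi = min(lo + 1024, m)
        block = np.abs(Z[:, lo:hi].T @ Z) / n
        mean_abs[lo:hi] = (block.sum(axis=1) - 1.0) / max(m - 1, 1)
    order = np.lexsort((np.arange(m), mean_abs))[::-1]  # ties -> later column first
    alive = np.ones(m, dtype=bool)
    cols = list(table.columns)
    for j in order:
        r = np.abs(Z[:, j] @ Z) / n
        r[j] = 0.0
        if (r[alive] > threshold).any():
            alive[j] = False
            dropped.append(cols[j])
    kept = [c for c, a in zip(cols, alive) if a]
    return table[kept], dropped


def lasso_select(
    table: pd.DataFrame,
    labels,
    folds: int = 10,
    seed: int = 0,
    coef_threshold: float = COEF_THRESHOLD,
    n_alphas: int = 100,
    Cs=None,
    rule: str = "1se",
) -> SelectionResult:
    """L1-logistic feature selection with CV-chosen penalty.

    ``table`` must contain training rows only; columns are z-scored by
    their training statistics before fitting. ``Cs`` overrides the
    default 100-point log-spaced inverse-penalty grid (e.g. to probe the
    strong-penalty limit). ``rule`` is "1se" (default; falls back to the
    CV minimum if the 1-SE penalty zeroes every coefficient) or "min".
    Folds are capped at the minority-class count so stratified CV stays
    well-defined on small cohorts.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; cannot run LASSO")
    X = table.to_numpy(dtype=float)
    mu, sc = X.mean(axis=0), X.std(axis=0)
    sc[sc == 0] = 1.0
    Z = (X - mu) / sc
    folds = max(2, min(folds, int(np.bincount(y).min())))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    grid = np.sort(np.asarray(Cs if Cs is not None else np.logspace(-4, 4, n_alphas)))

    def _fit(C, Xf, yf):
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=C, max_iter=2000, random_state=seed
        ).fit(Xf, yf)

    # CV deviance over the penalty path
    dev = np.zeros((folds, len(grid)))
    for f, (tr, va) in enumerate(cv.split(Z, y)):
        for j, C in enumerate(grid):
            m = _fit(C, Z[tr], y[tr])
            dev[f, j] = log_loss(y[va], m.predict_proba(Z[va])[:, 1], labels=[0, 1])
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    j_min = int(np.argmin(mean_dev))
    if rule == "1se":
        within = np.flatnonzero(mean_dev <= mean_dev[j_min] + se_dev[j_min])
        j_star = int(within.min())  # smallest C = strongest penalty within 1 SE
    elif rule == "min":
        j_star = j_min
    else:
        raise ValueError("rule must be '1se' or 'min'")
    model = _fit(grid[j_star], Z, y)
    if rule == "1se" and not (np.abs(model.coef_) >= coef_threshold).any():
        j_star = j_min  # 1-SE emptied the model; fall back to the CV minimum
        model = _fit(grid[j_star], Z, y)
    coefs = model.coef_.ravel()
    alpha = 1.0 / float(grid[j_star])
    kept = [c for c, b in zip(table.columns, coefs) if abs(b) >= coef_threshold]
    dropped = [c for c, b in zip(table.columns, coefs) if abs(b) < coef_threshold]
    if not kept:
        raise ValueError(
            "LASSO eliminated every feature at the CV-chosen penalty; "
            "the signal may be too weak -- consider a larger cohort or a "
            "smaller correlation threshold upstream"
        )
    return SelectionResult(
        kept_features=kept,
        lasso_alpha=alpha,
        coefficients={c: float(b) for c, b in zip(table.columns, coefs)},
        dropped_by_threshold=dropped,
        coef_threshold=coef_threshold,
        scaler_mean=mu,
        scaler_scale=sc,
    )


def select_features(
    table: pd.DataFrame,
    labels,
    corr_threshold: float = 0.9,
    folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Correlation filter followed by LASSO, on training rows only."""
    filtered, dropped_corr = correlation_filter(table, corr_threshold)
    res = lasso_select(filtered, labels, folds=folds, seed=seed)
    res.dropped_by_correlation = dropped_corr
    return res
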