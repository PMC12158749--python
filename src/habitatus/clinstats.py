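"""Clinicopathologic statistics and the risk-factor (C) model.

Implements the inferential tests used to compare covariates between
low (0-2 metastatic axillary nodes) and high (>=3) nodal-burden groups:
Pearson chi-square without continuity correction, Fisher's exact test,
and the pooled-variance independent t-test from group summaries. The C
model is a logistic regression on the covariates that pass a univariate
screen (p < 0.05) on the training cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ContingencyTable",
    "SummaryStats",
    "chi_square_p",
    "fisher_p",
    "t_test_from_summary",
    "categorical_p",
    "univariate_screen",
    "build_c_model",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for a 2 x R cross-tabulation of a covariate by burden group."""

    counts: tuple
    row_labels: tuple = ()
    col_labels: tuple = ()

    def as_array(self) -> np.ndarray:
        arr = np.asarray(self.counts, dtype=float)
        if arr.ndim != 2:
            raise ValueError("contingency table must be 2-D")
        if (arr < 0).any():
            raise ValueError("contingency table counts must be non-negative")
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise ValueError("contingency table has a zero margin")
        return arr


@dataclass(frozen=True)
class SummaryStats:
    """Mean +/- SD summary of a continuous covariate in one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("need n >= 2 per group")


def _as_table(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.as_array()
    return ContingencyTable(tuple(map(tuple, np.asarray(table)))).as_array()


def chi_square_p(table) -> float:
    """Two-sided Pearson chi-square p-value, no continuity correction.

    df = (rows-1)(cols-1).  The uncorrected variant is used throughout:
    it is the one consistent with the reference cross-tabulations this
    module is validated against.
    """
    arr = _as_table(table)
    _, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(p)


def fisher_p(table) -> float:
    """Fisher's exact two-sided p for a 2x2 table.

    Two-sidedness by summation of hypergeometric probabilities no larger
    than that of the observed table (the conventional rule, not tail
    doubling).
    """
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def expected_counts(table) -> np.ndarray:
    """Expected cell counts under independence (for the test-choice rule)."""
    arr = _as_table(table)
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()


def categorical_p(table) -> float:
    """Chi-square when all expected counts >= 5, else Fisher (2x2 only)."""
    arr = _as_table(table)
    if (expected_counts(arr) < 5).any() and arr.shape == (2, 2):
        return fisher_p(arr)
    return chi_square_p(arr)


def t_test_from_summary(a: SummaryStats, b: SummaryStats) -> float:
    """Two-sided pooled-variance independent t-test from group summaries."""
    if a.sd == 0 and b.sd == 0:
        return 1.0 if a.mean == b.mean else 0.0
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return float(res.pvalue)


def univariate_screen(
    covariates: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05
) -> list[str]:
    """Return covariate names univariately associated with the label.

    Categorical columns (object/category/bool or few unique values) are
    cross-tabulated against the binary label and tested with the
    chi-square/Fisher rule; numeric columns with the t-test.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels are degenerate (single class)")
    hits = []
    for col in covariates.columns:
        s = covariates[col]
        vals = s.to_numpy()
        if s.dtype.kind in "OUSb" or s.nunique() <= 4:
            tab = pd.crosstab(labels, s).to_numpy()
            if tab.shape[1] < 2:
                continue
            p = categorical_p(tab)
        else:
            g0, g1 = vals[labels == 0], vals[labels == 1]
            p = t_test_from_summary(
                SummaryStats(g0.mean(), g0.std(ddof=1), len(g0)),
                SummaryStats(g1.mean(), g1.std(ddof=1), len(g1)),
            )
        if p < alpha:
            hits.append(col)
    return hits


def build_c_model(covariates: pd.DataFrame, labels, split, seed: int = 0):
    """Fit the clinicopathologic risk-factor model.

    Screens covariates on the training cohort (p < 0.05), fits a logistic
    regression on the survivors, and evaluates on the held-out cohort.

    Returns (train_report, test_report, selected_covariates); reports are
    ``ModelReport`` instances from :mod:`habitatus.modeling`.
    """
    from .modeling import evaluate_fitted

    labels = np.asarray(labels).astype(int)
    idx = {cid: i for i, cid in enumerate(covariates.index)}
    tr = np.array([idx[c] for c in split.train_ids])
    te = np.array([idx[c] for c in split.test_ids])

    selected = univariate_screen(covariates.iloc[tr], labels[tr])
    if not selected:
        raise ValueError(
            "no covariate passed the univariate screen (p < 0.05); "
            "the C model needs at least one risk factor -- check label "
            "coding or provide candidate covariates with known association"
        )
    X = pd.get_dummies(covariates[selected], drop_first=True).to_numpy(float)
    model = LogisticRegression(max_iter=1000, random_state=seed)
    model.fit(X[tr], labels[tr])
    train_rep, test_rep = evaluate_fitted(
        model, X[tr], labels[tr], X[te], labels[te], model_name="C-model"
    )
    return train_rep, test_rep, selected
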