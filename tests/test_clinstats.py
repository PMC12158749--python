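"""Inferential statistics for the clinical covariate comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from habitatus.clinstats import (
    ContingencyTable,
    SummaryStats,
    build_c_model,
    categorical_p,
    chi_square_p,
    fisher_p,
    t_test_from_summary,
    univariate_screen,
)
from habitatus.dataio import split_cohort
from habitatus.synthdata import draw_clinical_cohort


@pytest.mark.parametrize(
    "table, expected",
    [
        ([[59, 19], [52, 34]], 0.038),  # clinical T stage by burden
        ([[84, 30], [27, 23]], 0.013),  # US-reported node status by burden
    ],
)
def test_chi_square_reproduces_reference_tables(table, expected):
    assert chi_square_p(table) == pytest.approx(expected, abs=5e-4)


def test_chi_square_independent_table_gives_p_one():
    assert chi_square_p([[50, 50], [50, 50]]) == pytest.approx(1.0)


def test_chi_square_rejects_zero_margin():
    with pytest.raises(ValueError, match="margin"):
        chi_square_p([[0, 0], [5, 5]])


def test_fisher_reproduces_reference_table():
    assert fisher_p([[24, 5], [6, 7]]) == pytest.approx(0.026, abs=5e-4)


def test_fisher_extreme_and_symmetric_tables():
    # perfectly discordant 10/10 table: only two tables are as extreme
    assert fisher_p([[10, 0], [0, 10]]) == pytest.approx(2.0 / comb(20, 10), rel=1e-9)
    assert fisher_p([[5, 5], [5, 5]]) == pytest.approx(1.0)


def _fisher_enumeration(table):
    """Independent oracle: sum hypergeometric P over tables with fixed
    margins whose probability does not exceed the observed table's."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


@pytest.mark.parametrize("seed", range(8))
def test_fisher_matches_full_enumeration(seed):
    rng = np.random.default_rng(seed)
    while True:
        t = rng.integers(0, 16, size=(2, 2))
        if t.sum() <= 60 and t.sum(0).min() > 0 and t.sum(1).min() > 0:
            break
    assert fisher_p(t) == pytest.approx(_fisher_enumeration(t), rel=1e-9)


def test_chi_square_and_fisher_converge_for_large_expected_counts():
    from habitatus.clinstats import expected_counts

    # Fisher's conservatism decays with the cell counts: the two tests
    # agree loosely once every expected count reaches 20 and tightly by 80
    rng = np.random.default_rng(3)
    for lo, hi, tol in ((25, 120, 0.03), (150, 400, 0.01)):
        done = 0
        while done < 5:
            t = rng.integers(lo, hi, size=(2, 2))
            if expected_counts(t).min() < (20 if lo < 150 else 80):
                continue
            assert abs(chi_square_p(t) - fisher_p(t)) < tol
            done += 1


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((51.33, 9.49, 111), (52.62, 12.10, 53), 0.459),  # age, training
        ((20.72, 7.628, 111), (23.11, 7.08, 53), 0.056),  # size, training
        ((19.8, 7.98, 30), (24.58, 6.80, 12), 0.075),  # size, test
    ],
)
def test_pooled_t_reproduces_reference_summaries(a, b, expected):
    # group summaries are printed rounded, so agreement is to ~2e-3
    p = t_test_from_summary(SummaryStats(*a), SummaryStats(*b))
    assert p == pytest.approx(expected, abs=2e-3)


def test_pooled_t_identical_groups():
    s = SummaryStats(10.0, 2.0, 30)
    assert t_test_from_summary(s, s) == pytest.approx(1.0)
    z = SummaryStats(5.0, 0.0, 10)
    assert t_test_from_summary(z, z) == 1.0


def test_categorical_p_switches_to_fisher_for_sparse_tables():
    sparse = [[2, 20], [3, 18]]  # expected counts < 5 in one column
    assert categorical_p(sparse) == pytest.approx(fisher_p(sparse))
    dense = [[40, 50], [45, 55]]
    assert categorical_p(dense) == pytest.approx(chi_square_p(dense))


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(((1, -2), (3, 4))).as_array()
    with pytest.raises(ValueError):
        SummaryStats(0.0, -1.0, 10)


def test_univariate_screen_finds_only_planted_risk_factors():
    rng = np.random.default_rng(2)
    covs, burden = draw_clinical_cohort(600, 0.316, rng)
    out = univariate_screen(pd.DataFrame(covs), burden)
    assert set(out) == {"cT", "us_ln_status"}


def test_c_model_perfect_predictor_gives_auc_one():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 60)
    covs = pd.DataFrame(
        {"oracle": y, "noise": rng.standard_normal(60)},
        index=[f"c{i}" for i in range(60)],
    )
    split = split_cohort(covs.index, y, ratio=0.8, seed=0)
    _, test_rep, selected = build_c_model(covs, y, split, seed=0)
    assert "oracle" in selected
    assert test_rep.auc == pytest.approx(1.0)


def test_c_model_on_synthetic_clinical_cohort():
    rng = np.random.default_rng(2)
    covs, burden = draw_clinical_cohort(600, 0.316, rng)
    df = pd.DataFrame(covs, index=[f"c{i}" for i in range(600)])
    split = split_cohort(df.index, burden, ratio=0.8, seed=10000)
    train_rep, test_rep, selected = build_c_model(df, burden, split, seed=0)
    assert set(selected) == {"cT", "us_ln_status"}
    # two binary risk factors give a modest but real discrimination
    assert 0.55 < test_rep.auc < 0.85
    assert test_rep.auc_ci_low <= test_rep.auc <= test_rep.auc_ci_high
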