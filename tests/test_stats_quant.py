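"""Calibration fitting, two-group tests, correlation, BH adjustment."""

from itertools import permutations

import numpy as np
import pytest
from scipy import stats as sps

from polysirm import (
    bh_adjust,
    compare_groups,
    correlate,
    fit_calibration,
    mann_whitney_exact,
)
from polysirm.stats_quant import exact_u_null_pvalues, significance_stars


# --------------------------------------------------------------------------
# calibration


def test_calibration_exact_line():
    c = fit_calibration([1, 10, 100], [2, 20, 200])
    assert c.slope == pytest.approx(2.0, abs=1e-10)
    assert c.intercept == pytest.approx(0.0, abs=1e-9)
    assert c.back_calculate(20.0) == pytest.approx(10.0, abs=1e-8)


def test_calibration_unweighted_matches_closed_form_ols():
    rng = np.random.default_rng(5)
    x = np.array([1.0, 2, 5, 10, 20, 50])
    y = 3.0 * x + 0.5 + rng.normal(0, 0.3, x.size)
    c = fit_calibration(x, y, weighting=None)
    slope = np.cov(x, y, bias=True)[0, 1] / np.var(x)
    intercept = y.mean() - slope * x.mean()
    assert c.slope == pytest.approx(slope, abs=1e-10)
    assert c.intercept == pytest.approx(intercept, abs=1e-10)


def test_weighted_fit_back_calculates_low_standards_under_constant_cv():
    # constant-CV noise: 1/x^2 weighting keeps the low end accurate where
    # the unweighted fit is dominated by the top standards
    rng = np.random.default_rng(11)
    x = np.array([0.5, 1, 5, 10, 50, 100, 500])
    rel_err_w, rel_err_o = [], []
    for _ in range(50):
        y = 2.0 * x * np.exp(rng.normal(0, 0.08, x.size))
        cw = fit_calibration(x, y, weighting="1/x2")
        co = fit_calibration(x, y, weighting=None)
        rel_err_w.append(abs(cw.back_calculate(y[0]) - x[0]) / x[0])
        rel_err_o.append(abs(co.back_calculate(y[0]) - x[0]) / x[0])
    assert np.median(rel_err_w) < 0.15
    assert np.median(rel_err_w) < np.median(rel_err_o)


def test_calibration_input_validation():
    with pytest.raises(ValueError):
        fit_calibration([1, 1, 1], [1, 2, 3])  # not 3 distinct concentrations
    with pytest.raises(ValueError):
        fit_calibration([0, 1, 2], [0, 1, 2])  # zero conc with 1/x^2
    with pytest.raises(ValueError):
        fit_calibration([1, 2, 3], [1, 2], weighting=None)


# --------------------------------------------------------------------------
# Mann-Whitney


def enumeration_oracle(a, b):
    """Independent exact oracle: permute group labels over pooled values."""
    pooled = list(a) + list(b)
    n_a = len(a)
    u_obs, _ = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    mu = n_a * len(b) / 2.0
    hits = total = 0
    seen = set()
    for perm in permutations(range(len(pooled)), n_a):
        key = tuple(sorted(perm))
        if key in seen:
            continue
        seen.add(key)
        total += 1
        ga = [pooled[i] for i in key]
        gb = [pooled[i] for i in range(len(pooled)) if i not in key]
        u, _ = sps.mannwhitneyu(ga, gb, alternative="two-sided", method="asymptotic")
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return hits / total


def test_mann_whitney_exact_textbook_case():
    u, p = mann_whitney_exact([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2 of 20 orderings are as extreme


@pytest.mark.parametrize(
    "a,b",
    [
        ([1, 2, 3], [4, 5, 6]),
        ([1.2, 5.5, 2.1, 8.0], [3.3, 0.5, 9.1]),
        ([1, 1, 2, 3], [2, 2, 4]),  # ties across groups
        ([0.1, 0.4, 0.9, 1.5, 2.2], [0.3, 0.8, 1.1, 4.0]),
    ],
)
def test_mann_whitney_exact_matches_enumeration_oracle(a, b):
    _, p = mann_whitney_exact(a, b)
    assert p == pytest.approx(enumeration_oracle(a, b), abs=1e-12)


def test_mann_whitney_exact_agrees_with_scipy_exact_without_ties():
    rng = np.random.default_rng(3)
    for _ in range(5):
        a, b = rng.normal(size=6), rng.normal(size=7)
        _, p = mann_whitney_exact(a, b)
        _, p_scipy = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(p_scipy, abs=1e-12)


def test_identical_groups_give_null_results():
    cmp_t = compare_groups([1.0, 2, 3], [1.0, 2, 3], test="student_t")
    assert cmp_t.statistic == pytest.approx(0.0)
    assert cmp_t.p_value == pytest.approx(1.0)
    cmp_u = compare_groups([2.0, 2, 2], [2.0, 2, 2], test="mann_whitney")
    assert cmp_u.p_value == pytest.approx(1.0)


def test_zero_variance_tie_warns_p_one():
    with pytest.warns(UserWarning, match="zero variance"):
        c = compare_groups([3.0, 3, 3], [3.0, 3, 3], test="student_t")
    assert c.p_value == 1.0


def test_exact_and_asymptotic_agree_at_n8(rng):
    diffs = []
    for _ in range(40):
        a, b = rng.normal(size=8), rng.normal(size=8)
        _, p_ex = mann_whitney_exact(a, b)
        _, p_as = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        diffs.append(abs(p_ex - p_as))
    assert np.median(diffs) < 0.01
    assert max(diffs) < 0.03


def test_welch_default_vs_pooled_flag():
    a = [1.0, 2.0, 3.0, 4.0]
    b = [10.0, 30.0, 50.0, 70.0, 90.0]
    welch = compare_groups(a, b).p_value
    pooled = compare_groups(a, b, equal_var=True).p_value
    t_w = sps.ttest_ind(a, b, equal_var=False).pvalue
    t_p = sps.ttest_ind(a, b, equal_var=True).pvalue
    assert welch == pytest.approx(t_w)
    assert pooled == pytest.approx(t_p)


def test_exact_u_null_pvalue_table_consistent_with_direct_exact(rng):
    table = exact_u_null_pvalues(5, 5)
    for _ in range(10):
        a, b = rng.normal(size=5), rng.normal(size=5)
        u, p = mann_whitney_exact(a, b)
        assert table[int(u)] == pytest.approx(p, abs=1e-12)


# --------------------------------------------------------------------------
# correlation, BH, stars


def test_correlation_perfect_monotone():
    x = np.array([1.0, 2, 3, 5, 8])
    assert correlate(x, x)[0] == pytest.approx(1.0)
    assert correlate(x, -x)[0] == pytest.approx(-1.0)
    assert correlate(x, 2 * x + 1, method="pearson")[0] == pytest.approx(1.0)


def test_correlation_null_is_centered(rng):
    rhos = [
        correlate(rng.normal(size=20), rng.normal(size=20))[0] for _ in range(500)
    ]
    assert abs(np.mean(rhos)) < 0.02


def test_correlation_rejects_constant_vector():
    with pytest.raises(ValueError):
        correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_bh_adjustment_monotone_and_bounded(rng):
    p = rng.uniform(size=30)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in raw p


def test_significance_stars_thresholds():
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(4e-4) == "***"
    assert significance_stars(4e-5) == "****"
    assert significance_stars(0.2) == "ns"
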