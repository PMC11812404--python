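"""Two-group statistics and LC-MS/MS calibration used across the pipeline.

Covers the comparisons reported throughout the study — Student's t for the
small paired human/mouse enrichment panels, Mann-Whitney for the unpaired
IBD metabolite tables — plus weighted (1/x^2) least-squares calibration for
absolute quantitation of PUT and SPD against an internal standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.api import WLS, add_constant
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "GroupComparison",
    "compare_groups",
    "correlate",
    "bh_adjust",
    "significance_stars",
    "mann_whitney_exact",
    "exact_u_null_pvalues",
]


# --------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationCurve:
    """Linear calibration of analyte/IS area ratio vs concentration."""

    concentrations: np.ndarray
    ratios: np.ndarray
    slope: float
    intercept: float
    weighting: str | None  # "1/x2" or None (ordinary least squares)

    def back_calculate(self, ratio) -> np.ndarray:
        """Concentration(s) predicted from observed area ratio(s)."""
        return (np.asarray(ratio, dtype=float) - self.intercept) / self.slope


def fit_calibration(
    concentrations,
    ratios,
    weighting: str | None = "1/x2",
) -> CalibrationCurve:
    """Weighted least-squares calibration line.

    ``weighting="1/x2"`` minimizes sum (1/x_i^2)(y_i - a - b x_i)^2, the
    standard choice when area CV is roughly constant across the calibration
    range (heteroscedastic noise); ``weighting=None`` is ordinary least
    squares.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and ratios must be equal-length 1-D")
    if np.unique(x).size < 3:
        raise ValueError("calibration needs >= 3 distinct concentrations")
    if weighting == "1/x2":
        if np.any(x <= 0):
            raise ValueError("1/x^2 weighting requires strictly positive concentrations")
        w = 1.0 / x**2
    elif weighting is None:
        w = np.ones_like(x)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    fit = WLS(y, add_constant(x), weights=w).fit()
    intercept, slope = fit.params
    if not np.isfinite(slope) or slope == 0:
        raise ValueError("degenerate calibration: zero or non-finite slope")
    return CalibrationCurve(x, y, float(slope), float(intercept), weighting)


# --------------------------------------------------------------------------
# two-group comparisons


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    metabolite: str
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float
    stars: str
    adjusted_p: float | None = None


def _u_statistic(pooled_ranks: np.ndarray, idx_a, n_a: int) -> float:
    return float(pooled_ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney test by full enumeration.

    Enumerates all C(n_a+n_b, n_a) group assignments of the pooled values
    (midranks, so ties — including fully identical groups — are handled) and
    computes P(|U - n_a n_b / 2| >= |u_obs - n_a n_b / 2|) under the
    exchangeable null. Intended for small samples (both groups <= 8).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(n_a), n_a)
    mu = n_a * n_b / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n_a + n_b), n_a):
        total += 1
        if abs(_u_statistic(ranks, idx, n_a) - mu) >= dev - 1e-9:
            hits += 1
    return u_obs, hits / total


def exact_u_null_pvalues(n_a: int, n_b: int) -> np.ndarray:
    """Exact two-sided p for every U value, tie-free null, indexable by U.

    Convenience for vectorized simulation with continuous data: the null U
    distribution is obtained by enumeration over rank assignments once, and
    ``out[U]`` is the two-sided p-value.
    """
    ranks = np.arange(1, n_a + n_b + 1, dtype=float)
    counts = np.zeros(n_a * n_b + 1)
    for idx in combinations(range(n_a + n_b), n_a):
        counts[int(_u_statistic(ranks, idx, n_a))] += 1
    counts /= counts.sum()
    mu = n_a * n_b / 2.0
    dev = np.abs(np.arange(n_a * n_b + 1) - mu)
    return np.array([counts[dev >= d - 1e-9].sum() for d in dev])


def compare_groups(
    values_a,
    values_b,
    test: str = "student_t",
    metabolite: str = "",
    group_a: str = "a",
    group_b: str = "b",
    equal_var: bool = False,
    exact_max_n: int = 8,
) -> GroupComparison:
    """Two-sided two-group comparison.

    ``student_t`` defaults to Welch's unequal-variance form (``equal_var``
    restores the classic pooled test). ``mann_whitney`` uses the exact
    enumeration null when both groups have <= ``exact_max_n`` observations
    and the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "student_t":
        if a.size < 2 or b.size < 2:
            raise ValueError("t-test needs >= 2 values per group")
        if np.var(a) == 0 and np.var(b) == 0:
            warnings.warn(
                "zero variance in both groups; t statistic undefined, p set to 1",
                stacklevel=2,
            )
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
    elif test == "mann_whitney":
        if a.size < 1 or b.size < 1:
            raise ValueError("Mann-Whitney needs >= 1 value per group")
        if a.size <= exact_max_n and b.size <= exact_max_n:
            stat, p = mann_whitney_exact(a, b)
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    else:
        raise ValueError(f"unknown test {test!r}")
    p = float(min(p, 1.0))
    return GroupComparison(
        metabolite=metabolite,
        group_a=group_a,
        group_b=group_b,
        test=test,
        statistic=float(stat),
        p_value=p,
        stars=significance_stars(p),
    )


def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    """Two-sided correlation (rho, p) between equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("correlate needs equal-length 1-D vectors, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    if method == "spearman":
        r, p = sps.spearmanr(x, y)
    elif method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
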