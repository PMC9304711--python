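"""Group-comparison statistics used throughout the pipeline.

Two-sided Mann-Whitney U (exact enumeration when both groups are small,
normal approximation with tie and continuity correction otherwise),
two-sided pooled-variance t-test, chi-square on count tables, and Pearson
correlation.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

EXACT_MAX_N = 8  # both groups at or below this size -> exact enumeration


@dataclass
class GroupComparison:
    statistic_name: str
    estimate: float
    p_value: float
    sidedness: str = "two-sided"
    summary_a: dict = field(default_factory=dict)
    summary_b: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def _summary(x: np.ndarray) -> dict:
    return {
        "n": int(x.size),
        "median": float(np.median(x)),
        "iqr": float(np.subtract(*np.percentile(x, [75, 25]))),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
    }


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U by full enumeration of group assignments.

    Uses midranks, so it is defined under ties.  p = P(|U - mn/2| >= |u - mn/2|)
    over all C(n+m, n) equally likely assignments of the pooled values to
    group A.  Returns (U of group a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    center = n * m / 2
    dev_obs = abs(u_obs - center)
    total = 0
    extreme = 0
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - center) >= dev_obs - 1e-12:
            extreme += 1
    return float(u_obs), extreme / total


def mann_whitney(a, b) -> GroupComparison:
    """Two-sided Mann-Whitney U; exact path when both n <= 8."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values for a rank test")
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N:
        u, p = mann_whitney_exact(a, b)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        u, p = float(res.statistic), float(res.pvalue)
    return GroupComparison("mann_whitney_u", u, min(p, 1.0),
                           summary_a=_summary(a), summary_b=_summary(b))


def t_test(a, b) -> GroupComparison:
    """Two-sided pooled-variance t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values for a t-test")
    res = sps.ttest_ind(a, b, equal_var=True)
    p = float(res.pvalue)
    if np.isnan(p):  # zero pooled variance with equal means
        p = 1.0
    return GroupComparison("t_test", float(res.statistic), p,
                           summary_a=_summary(a), summary_b=_summary(b))


def chi_square(table) -> GroupComparison:
    """Chi-square test of independence on a count table (no Yates correction)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("chi_square expects a non-negative 2-D count table")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return GroupComparison(
        "chi_square", float(stat), float(p),
        summary_a={"row_totals": table.sum(axis=1).tolist()},
        summary_b={"col_totals": table.sum(axis=0).tolist()},
    )


def pearson(x, y) -> GroupComparison:
    """Pearson product-moment correlation with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs paired arrays of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return GroupComparison("pearson_r", float(res.statistic), float(res.pvalue),
                           summary_a=_summary(x), summary_b=_summary(y))


def compare_groups(values_a, values_b, test: str) -> GroupComparison:
    """Dispatch by test name: mann_whitney_u | t_test | chi_square | pearson_r.

    For chi_square, ``values_a`` is the count table and ``values_b`` ignored;
    for pearson_r the two arguments are the paired variables.
    """
    if test == "mann_whitney_u":
        return mann_whitney(values_a, values_b)
    if test == "t_test":
        return t_test(values_a, values_b)
    if test == "chi_square":
        return chi_square(values_a)
    if test == "pearson_r":
        return pearson(values_a, values_b)
    raise ValueError(f"unknown test {test!r}")
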