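"""Arm-level statistics for lesion quantification studies.

Covers the comparisons typical of a two/three-arm rodent study: incidence
percentages from affected counts, a pooled-variance two-tailed t-test
(computable from printed group summaries alone), the 2x2 chi-square and
Fisher exact tests for incidence tables, and one-way ANOVA with
Bonferroni-corrected pairwise post hoc t-tests.  Distribution functions
come from scipy.stats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "incidence_percent",
    "summarize_arm",
    "pooled_t_test",
    "welch_t_test",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "one_way_anova",
    "posthoc_pairwise",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-arm aggregate: size, affected count, mean ± sample SD."""

    arm_name: str
    n: int
    k_affected: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not 0 <= self.k_affected <= self.n:
            raise ValueError("k_affected must be in [0, n]")

    @property
    def incidence_pct(self) -> float:
        return incidence_percent(self.k_affected, self.n)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    test_name: str
    note: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError("p_value must be in [0, 1]")


def incidence_percent(k: int, n: int) -> float:
    """Percentage of affected animals, one decimal, round half up."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    return math.floor(1000.0 * k / n + 0.5) / 10.0


def summarize_arm(
    arm_name: str,
    values: Sequence[float],
    affected_rule: Callable[[float], bool] = lambda v: v > 0,
) -> GroupSummary:
    """Mean, sample SD (n−1 denominator) and affected count for one arm."""
    vals = np.asarray(list(values), dtype=np.float64)
    if vals.size == 0:
        raise ValueError("empty arm")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return GroupSummary(
        arm_name=arm_name,
        n=int(vals.size),
        k_affected=int(sum(bool(affected_rule(v)) for v in vals)),
        mean=float(vals.mean()),
        sd=sd,
    )


def pooled_t_test(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TestResult:
    """Two-tailed Student's t-test from group summaries, pooled variance.

    sp² = ((n1−1)s1² + (n2−1)s2²)/(n1+n2−2); t = (m1−m2)/(sp·√(1/n1+1/n2));
    df = n1+n2−2.  Degenerate inputs (both SDs zero) are flagged: p = 1 when
    the means agree, p = 0 otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be nonnegative")
    df = n1 + n2 - 2
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return TestResult(0.0, df, 1.0, "pooled t", note="degenerate: zero variance")
        return TestResult(
            math.copysign(math.inf, m1 - m2), df, 0.0, "pooled t",
            note="degenerate: zero variance, distinct means",
        )
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(t, df, min(p, 1.0), "pooled t")


def welch_t_test(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TestResult:
    """Welch's unequal-variance t-test from group summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 == 0 and s2 == 0:
        return pooled_t_test(m1, s1, n1, m2, s2, n2)
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(t, df, min(p, 1.0), "welch t")


def _check_2x2(a: int, b: int, c: int, d: int) -> None:
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("all margins of the 2x2 table must be positive")


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table (df = 1), no continuity correction
    by default; ``yates=True`` applies the Yates correction."""
    _check_2x2(a, b, c, d)
    n = a + b + c + d
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2.0, 0.0)
    chi2 = n * num**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = float(sps.chi2.sf(chi2, 1))
    return TestResult(chi2, 1, p, "chi-square (Yates)" if yates else "chi-square")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Fisher's exact test, two-sided: the p-value sums the hypergeometric
    probabilities of all tables (margins fixed) no more probable than the
    observed one.  The reported statistic is the sample odds ratio."""
    _check_2x2(a, b, c, d)
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult(float(odds), 0, float(p), "fisher exact")


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA: F = MS_between / MS_within, df = (k−1, N−k).

    When every observation is identical, F is undefined (flagged, p = 1);
    equal group means with nonzero spread give F = 0, p = 1.
    """
    arrs = [np.asarray(list(g), dtype=np.float64) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 values")
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    grand = float(np.concatenate(arrs).mean())
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrs)
    df = (k - 1, n_total - k)
    if ss_within == 0:
        if ss_between == 0:
            return TestResult(
                math.nan, df, 1.0, "one-way ANOVA", note="degenerate: all values identical"
            )
        return TestResult(
            math.inf, df, 0.0, "one-way ANOVA", note="degenerate: zero within-group variance"
        )
    f = (ss_between / df[0]) / (ss_within / df[1])
    p = float(sps.f.sf(f, df[0], df[1]))
    return TestResult(float(f), df, p, "one-way ANOVA")


def posthoc_pairwise(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
) -> list[tuple[str, str, TestResult]]:
    """Bonferroni-corrected pairwise pooled t-tests (the post hoc step)."""
    arrs = [np.asarray(list(g), dtype=np.float64) for g in groups]
    if names is None:
        names = [f"group{i + 1}" for i in range(len(arrs))]
    m = len(arrs) * (len(arrs) - 1) // 2
    out = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            a, b = arrs[i], arrs[j]
            res = pooled_t_test(
                float(a.mean()), float(a.std(ddof=1)), a.size,
                float(b.mean()), float(b.std(ddof=1)), b.size,
            )
            adj = min(res.p_value * m, 1.0)
            out.append(
                (
                    names[i],
                    names[j],
                    TestResult(res.statistic, res.df, adj, "pooled t (Bonferroni)", res.note),
                )
            )
    return out
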