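"""Two- and k-group comparisons used throughout the pipeline.

Retraction velocities and relaxation times are compared with the
nonparametric Mann-Whitney U test; apical domain sizes with one-way ANOVA;
fluorescence-intensity ratios with the pooled-variance Student t-test.
Effect sizes are reported as the percent change of the treated-group mean
relative to the control-group mean, and summaries as mean +/- sample
standard deviation with n. All p values are two-sided; no multiple-testing
correction is applied (none is in the protocol being implemented), which
the report records.

The Mann-Whitney p is exact (full enumeration of the U null distribution)
for small tie-free samples (combined n <= 14) and otherwise uses the
normal approximation with tie and continuity corrections; two-sided p is
twice the one-sided tail, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "GroupComparison",
    "SampleSummary",
    "mann_whitney_u",
    "students_t",
    "one_way_anova",
    "percent_change",
    "summarize",
    "compare_groups",
    "significance_stars",
    "EXACT_MW_MAX_N",
]

EXACT_MW_MAX_N = 14   # combined-n threshold for exact enumeration


@dataclass
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values: need a 1-D non-empty sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values: must be finite")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class SampleSummary:
    label: str
    mean: float
    sd: float          # sample (n-1) s.d.; nan when n < 2
    n: int


@dataclass
class GroupComparison:
    """Two-condition report: summaries, percent change and a test."""

    labels: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]
    percent_change: float      # % of control (first group = control)
    statistic: float
    p_value: float
    test_name: str
    stars: str = ""
    degenerate: bool = False
    notes: str = "no multiple-testing correction applied"


def _check_test_sample(s: GroupSample) -> None:
    if s.n < 2:
        raise ValueError(f"{s.label}: need n >= 2 for a test")


def mann_whitney_u(x: GroupSample, y: GroupSample) -> tuple[float, float]:
    """Mann-Whitney U (midranks) with exact or corrected-normal two-sided p.

    Exact enumeration when the combined n <= 14 and there are no ties;
    otherwise the normal approximation with tie correction and continuity
    correction. Identical degenerate samples give p = 1.
    """
    _check_test_sample(x)
    _check_test_sample(y)
    pooled = np.concatenate([x.values, y.values])
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence of any shift
        return float(x.n * y.n / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x.values, y.values, alternative="two-sided",
                           method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def students_t(x: GroupSample, y: GroupSample) -> tuple[float, float]:
    """Pooled-variance two-sample t-test, df = n1 + n2 - 2, two-sided."""
    _check_test_sample(x)
    _check_test_sample(y)
    sx = x.values.var(ddof=1)
    sy = y.values.var(ddof=1)
    if sx == 0 and sy == 0:
        if x.values.mean() == y.values.mean():
            return 0.0, 1.0
        raise ValueError("degenerate: zero pooled variance with unequal means")
    res = sps.ttest_ind(x.values, y.values, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups: Sequence[GroupSample]) -> tuple[float, float]:
    """Standard between/within decomposition; p from F(df_b, df_w)."""
    if len(groups) < 2:
        raise ValueError("groups: need at least 2 groups")
    for g in groups:
        _check_test_sample(g)
    within_var = sum(float(g.values.var(ddof=1)) for g in groups)
    if within_var == 0:
        means = [g.values.mean() for g in groups]
        if np.ptp(means) == 0:
            return 0.0, 1.0
        raise ValueError("degenerate: zero within-group variance, unequal means")
    res = sps.f_oneway(*[g.values for g in groups])
    return float(res.statistic), float(res.pvalue)


def percent_change(treated: GroupSample, control: GroupSample) -> float:
    """100 * (mean(treated) - mean(control)) / mean(control)."""
    mc = control.values.mean()
    if mc == 0:
        raise ValueError("control: mean is zero, percent change undefined")
    return float(100.0 * (treated.values.mean() - mc) / mc)


def summarize(sample: GroupSample) -> SampleSummary:
    """Mean, sample (n-1) s.d. and n; s.d. is nan for a single observation."""
    sd = float(sample.values.std(ddof=1)) if sample.n >= 2 else float("nan")
    return SampleSummary(label=sample.label, mean=float(sample.values.mean()),
                         sd=sd, n=sample.n)


def significance_stars(p: float) -> str:
    """Figure-legend convention: * / ** / *** / **** at 0.05/0.01/0.001/0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p <= cut:
            return stars
    return "ns"


def compare_groups(control: GroupSample, treated: GroupSample,
                   test: str = "mann-whitney") -> GroupComparison:
    """Full two-condition report with the chosen test.

    ``test`` is ``"mann-whitney"`` or ``"t"``; the control group comes
    first and defines the percent-change baseline.
    """
    if test == "mann-whitney":
        stat, p = mann_whitney_u(control, treated)
        name = "Mann-Whitney U"
    elif test == "t":
        stat, p = students_t(control, treated)
        name = "Student's t (pooled)"
    else:
        raise ValueError(f"test: unknown test {test!r}")
    sc, st_ = summarize(control), summarize(treated)
    pooled = np.concatenate([control.values, treated.values])
    return GroupComparison(
        labels=(control.label, treated.label),
        means=(sc.mean, st_.mean), sds=(sc.sd, st_.sd), ns=(sc.n, st_.n),
        percent_change=percent_change(treated, control),
        statistic=stat, p_value=p, test_name=name,
        stars=significance_stars(p), degenerate=bool(np.ptp(pooled) == 0),
    )
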