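"""Group statistics: one-way ANOVA (raw data or printed summaries),
Tukey-Kramer post hoc, paired t-tests, and pooled two-sample t-tests.

Published group results in this field are usually printed as mean +/- SD
with n per group. Classical one-way ANOVA, the Tukey-Kramer procedure and
the pooled two-sample t-test are all exact functions of those moments, so
every routine here has a ``*_from_summary`` form operating directly on
(mean, sd, n) triples; the raw-data forms reduce to them. SDs are treated
as sample (n-1) standard deviations throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "TukeyResult",
    "TTestResult",
    "summarize",
    "anova_from_summary",
    "anova_oneway",
    "tukey_hsd_from_summary",
    "paired_t",
    "two_sample_t_from_summary",
    "null_anova_rejection_rate",
]


@dataclass(frozen=True)
class GroupSummary:
    """Printed summary of one group: label, n, mean, sample SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2, got n={self.n}")
        if not self.sd >= 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    ms_within: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class TukeyResult:
    """All-pairs Tukey-Kramer comparisons.

    ``pairs`` maps an unordered label pair to
    ``{"mean_diff", "q", "p"}``; adjusted p comes from the studentized
    range distribution with k groups and the ANOVA's within df.
    """

    pairs: dict[frozenset, dict[str, float]]
    k: int
    df_within: int

    def p_value(self, a: str, b: str) -> float:
        return self.pairs[frozenset((a, b))]["p"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def summarize(values, label: str = "") -> GroupSummary:
    """Moments of a raw sample as a :class:`GroupSummary` (sample SD)."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"group {label!r}: need a 1D sample with n >= 2")
    return GroupSummary(label=label, n=arr.size, mean=float(arr.mean()),
                        sd=float(arr.std(ddof=1)))


def anova_from_summary(groups: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA computed from per-group (mean, sd, n).

    With grand mean m = sum(n_i m_i)/N: MSB = sum n_i (m_i - m)^2 / (k-1),
    MSW = sum (n_i - 1) s_i^2 / (N - k), F = MSB/MSW, and p is the upper
    tail of F(k-1, N-k). All s_i = 0 with equal means leaves F undefined
    (0/0) and yields an explicitly degenerate result.
    """
    if len(groups) < 2:
        raise ValueError(f"need at least 2 groups, got {len(groups)}")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    s = np.array([g.sd for g in groups], dtype=float)
    k = len(groups)
    N = n.sum()
    df_between = k - 1
    df_within = int(N - k)
    grand = float((n * m).sum() / N)
    msb = float((n * (m - grand) ** 2).sum() / df_between)
    msw = float(((n - 1) * s**2).sum() / df_within)
    if msw == 0.0:
        if msb == 0.0:
            # no variance anywhere: F = 0/0
            return AnovaResult(math.nan, df_between, df_within, 0.0, math.nan, degenerate=True)
        return AnovaResult(math.inf, df_between, df_within, 0.0, 0.0, degenerate=True)
    F = msb / msw
    p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(F, df_between, df_within, msw, max(p, np.finfo(float).tiny))


def anova_oneway(groups: list, labels: list[str] | None = None) -> AnovaResult:
    """One-way ANOVA on raw per-group value lists.

    Identical (to floating-point precision) to :func:`anova_from_summary`
    applied to the groups' moments.
    """
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    if len(groups) < 2:
        raise ValueError(f"need at least 2 groups, got {len(groups)}")
    return anova_from_summary([summarize(g, lab) for g, lab in zip(groups, labels)])


def tukey_hsd_from_summary(
    groups: list[GroupSummary],
    ms_within: float | None = None,
    df_within: int | None = None,
) -> TukeyResult:
    """Tukey-Kramer all-pairs comparisons from group summaries.

    q_ij = |m_i - m_j| / sqrt((MSW/2)(1/n_i + 1/n_j)); the adjusted p is the
    upper tail of the studentized range distribution with k groups and
    ``df_within`` degrees of freedom (the Kramer form handles unequal n).
    MSW/df default to the one-way ANOVA of the same summaries.
    """
    if ms_within is None or df_within is None:
        res = anova_from_summary(groups)
        ms_within = res.ms_within if ms_within is None else ms_within
        df_within = res.df_within if df_within is None else df_within
    if not ms_within > 0:
        raise ValueError(f"ms_within must be positive, got {ms_within}")
    k = len(groups)
    pairs: dict[frozenset, dict[str, float]] = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            se = math.sqrt((ms_within / 2.0) * (1.0 / a.n + 1.0 / b.n))
            diff = a.mean - b.mean
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_within))
            pairs[frozenset((a.label, b.label))] = {
                "mean_diff": diff,
                "q": q,
                "p": min(max(p, 0.0), 1.0),
            }
    return TukeyResult(pairs=pairs, k=k, df_within=int(df_within))


def paired_t(values_a, values_b) -> TTestResult:
    """Classical paired t-test on matched per-subject values (two-tailed).

    Zero-variance differences produce an explicitly degenerate result
    instead of a division blow-up: t = 0, p = 1 when all differences are
    zero; otherwise t = +/-inf, p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired samples must be matched 1D lists, got {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError(f"need at least 2 pairs, got {a.size}")
    d = a - b
    df = a.size - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d[0] == 0.0:
            return TTestResult(0.0, df, 1.0, degenerate=True)
        return TTestResult(math.copysign(math.inf, d[0]), df, 0.0, degenerate=True)
    t = float(d.mean() / (sd / math.sqrt(a.size)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t, df, p)


def two_sample_t_from_summary(a: GroupSummary, b: GroupSummary) -> TTestResult:
    """Pooled-variance Student t-test from two group summaries (two-tailed).

    Pooled (not Welch): s_p^2 = ((n_a-1)s_a^2 + (n_b-1)s_b^2) / (n_a+n_b-2),
    df = n_a + n_b - 2.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0.0:
        if a.mean == b.mean:
            return TTestResult(0.0, df, 1.0, degenerate=True)
        return TTestResult(math.copysign(math.inf, a.mean - b.mean), df, 0.0, degenerate=True)
    t = float((a.mean - b.mean) / math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t, df, p)


def null_anova_rejection_rate(
    n_groups: int = 4,
    n_per_group: int = 8,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the one-way ANOVA under the null.

    Simulates ``n_reps`` cohorts of ``n_groups`` equal-mean normal groups
    (n per group as in the eight-animal, four-defect design) and returns the
    fraction with p < alpha. Fully vectorized; used to check the test's
    calibration (should be ~alpha).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_reps, n_groups, n_per_group))
    m = x.mean(axis=2)
    v = x.var(axis=2, ddof=1)
    grand = m.mean(axis=1)
    df_b = n_groups - 1
    df_w = n_groups * (n_per_group - 1)
    msb = n_per_group * ((m - grand[:, None]) ** 2).sum(axis=1) / df_b
    msw = v.mean(axis=1)
    F = msb / msw
    p = sps.f.sf(F, df_b, df_w)
    return float((p < alpha).mean())
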