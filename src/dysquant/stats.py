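"""Statistical layer: reproducibility, normality, and group comparisons.

Reproducibility of repeated quantifications of the same biopsies is
summarised by the intraclass correlation coefficient, model ICC(2,1):
two-way random effects, absolute agreement, single measures, computed here
from the ANOVA mean squares with the standard F-based 95% interval.
Group differences in raw per-ROI intensities use the Kruskal-Wallis omnibus
test plus pairwise unpaired Wilcoxon rank-sum (Mann-Whitney) tests, reported
unadjusted by default (Holm adjustment available).  Manual-vs-automatic
method equivalence uses the two-sample pooled-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ICCResult",
    "GroupComparison",
    "MethodComparison",
    "icc_absolute_agreement",
    "normality_test",
    "compare_groups",
    "compare_methods",
]


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int
    model_label: str = "two-way random, absolute agreement, single measures (ICC(2,1))"


@dataclass
class GroupComparison:
    omnibus_stat: float
    omnibus_p: float
    pairwise: list[tuple[str, str, float, float]]  # (a, b, U statistic, p)
    group_summaries: dict[str, tuple[float, float, int]]  # mean, SE, n
    adjusted: bool = False


@dataclass(frozen=True)
class MethodComparison:
    t_stat: float
    p: float
    n_manual: int
    n_auto: int
    mean_difference: float


def icc_absolute_agreement(matrix: np.ndarray, confidence: float = 0.95) -> ICCResult:
    """ICC(2,1) from a complete subjects x raters matrix.

    estimate = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    with MSR/MSC/MSE the between-subject, between-rater and residual mean
    squares of the two-way ANOVA; the confidence interval follows the
    standard F-based construction for the absolute-agreement single-measures
    form.  The estimate is clipped to [-1, 1].
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a subjects x raters matrix with >= 2 of each")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise ValueError("degenerate variance structure (constant matrix?)")
    icc = float(np.clip((msr - mse) / denom, -1.0, 1.0))

    alpha = 1.0 - confidence
    if mse == 0 and msc <= mse:
        lo = hi = icc  # perfect agreement: interval collapses
    else:
        a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isinf(a) or np.isinf(b):
            lo = hi = icc
        else:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_hi = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_lo * mse) / (
                f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f_hi * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_hi * msr
            )
    lo = float(np.clip(lo, -1.0, min(icc, 1.0)))
    hi = float(np.clip(hi, max(icc, -1.0), 1.0))
    return ICCResult(estimate=icc, ci_low=lo, ci_high=hi, n_subjects=n, n_raters=k)


def normality_test(values: Sequence[float]) -> float:
    """Shapiro-Wilk p-value for 3 <= n <= 5000 samples."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={v.size}")
    if np.ptp(v) == 0:
        raise ValueError("normality test undefined for constant input")
    return float(sps.shapiro(v).pvalue)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    holm_adjust: bool = False,
) -> GroupComparison:
    """Kruskal-Wallis omnibus plus all pairwise two-sided rank-sum tests.

    Raw per-ROI intensities are compared unpaired; p-values are reported
    unadjusted unless `holm_adjust` is set.  Results are invariant to the
    order groups are supplied in (pairs are emitted in sorted label order).
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has n={v.size} < 3")
    labels = sorted(groups)
    h, p = sps.kruskal(*(groups[g] for g in labels))
    pairs = []
    for a, b in combinations(labels, 2):
        res = sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        pairs.append([a, b, float(res.statistic), float(res.pvalue)])
    if holm_adjust and pairs:
        ps = np.array([q[3] for q in pairs])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * ps[idx])
            adj[idx] = min(running, 1.0)
        for q, ap in zip(pairs, adj):
            q[3] = float(ap)
    summaries = {
        g: (float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size)), int(v.size))
        for g, v in groups.items()
    }
    return GroupComparison(
        omnibus_stat=float(h),
        omnibus_p=float(p),
        pairwise=[tuple(q) for q in pairs],
        group_summaries=summaries,
        adjusted=holm_adjust,
    )


def compare_methods(
    manual: Sequence[float], auto: Sequence[float]
) -> MethodComparison:
    """Two-sided pooled-variance t-test of manual vs automatic biopsy means."""
    a = np.asarray(manual, dtype=float)
    b = np.asarray(auto, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per method")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise ValueError("zero pooled variance: all values identical")
    res = sps.ttest_ind(a, b, equal_var=True)
    return MethodComparison(
        t_stat=float(res.statistic),
        p=float(res.pvalue),
        n_manual=int(a.size),
        n_auto=int(b.size),
        mean_difference=float(a.mean() - b.mean()),
    )
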