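"""Normality-driven two-group test selection.

The comparison rule used throughout the study's panels: test each sample
for normality — D'Agostino–Pearson when n ≥ 8, Shapiro–Wilk when n < 8 —
and (a) fall back to the Mann–Whitney U-test if either sample rejects at
``alpha_norm``, otherwise (b) apply Welch's correction if a two-sided
F-test rejects equal variances at ``alpha_var``, otherwise (c) use
Student's t.  All tests are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "compare_two_groups",
    "dispatch_report",
    "one_sample_t",
]

DAGOSTINO_MIN_N = 8


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of one dispatched two-group comparison."""

    chosen_test: str  # student_t | welch_t | mann_whitney
    normality_test_used: str  # dagostino_pearson | shapiro_wilk (per the larger rule)
    p_value: float
    statistic: float
    normality_p_a: Optional[float]
    normality_p_b: Optional[float]
    variance_p: Optional[float]
    n_a: int
    n_b: int
    label: Optional[str] = None
    two_sided: bool = True


def _normality_p(x: np.ndarray) -> tuple[float, str]:
    if x.size >= DAGOSTINO_MIN_N:
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="kurtosistest")
            return float(stats.normaltest(x).pvalue), "dagostino_pearson"
    return float(stats.shapiro(x).pvalue), "shapiro_wilk"


def _variance_f_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test for equal variances."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    cdf = stats.f.cdf(f, dfa, dfb)
    return float(2 * min(cdf, 1 - cdf))


def compare_two_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha_norm: float = 0.05,
    alpha_var: float = 0.05,
    label: Optional[str] = None,
) -> GroupComparison:
    """Compare two samples with the normality-dispatch rule.

    Each sample needs n ≥ 3.  Constant samples defeat the normality tests,
    so they fall back to Mann–Whitney with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 observations")

    norm_name = "dagostino_pearson" if max(a.size, b.size) >= DAGOSTINO_MIN_N else "shapiro_wilk"
    if a.var() == 0 or b.var() == 0:
        warnings.warn("constant sample; falling back to Mann-Whitney")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison(
            "mann_whitney", norm_name, float(res.pvalue), float(res.statistic),
            None, None, None, a.size, b.size, label,
        )

    pa, name_a = _normality_p(a)
    pb, name_b = _normality_p(b)
    norm_name = name_a if a.size >= b.size else name_b

    if pa < alpha_norm or pb < alpha_norm:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison(
            "mann_whitney", norm_name, float(res.pvalue), float(res.statistic),
            pa, pb, None, a.size, b.size, label,
        )

    p_var = _variance_f_p(a, b)
    if p_var < alpha_var:
        res = stats.ttest_ind(a, b, equal_var=False)
        chosen = "welch_t"
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        chosen = "student_t"
    return GroupComparison(
        chosen, norm_name, float(res.pvalue), float(res.statistic),
        pa, pb, p_var, a.size, b.size, label,
    )


def dispatch_report(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tabulate a batch of dispatched comparisons (one row per panel)."""
    cols = [
        "label", "chosen_test", "normality_test_used", "p_value", "statistic",
        "normality_p_a", "normality_p_b", "variance_p", "n_a", "n_b",
    ]
    return pd.DataFrame([{c: getattr(gc, c) for c in cols} for gc in comparisons], columns=cols)


def one_sample_t(sample: Sequence[float], popmean: float) -> tuple[float, float]:
    """Two-sided one-sample t-test; returns (statistic, p)."""
    res = stats.ttest_1samp(np.asarray(sample, dtype=float), popmean)
    return float(res.statistic), float(res.pvalue)
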