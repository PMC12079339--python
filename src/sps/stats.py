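"""Shared statistical primitives.

Summary-statistic t-tests (for comparisons that are only available as
printed means/SDs), Cohen's d variants, paired t-tests, and
Benjamini-Hochberg FDR control. These are thin, well-specified wrappers
around scipy / statsmodels so that every module in the package applies
exactly the same conventions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SummaryStats",
    "TTestResult",
    "two_sample_t_from_summary",
    "cohens_d_from_summary",
    "paired_t",
    "bh_fdr",
]


@dataclass(frozen=True)
class SummaryStats:
    """Mean, SD and n of one group, in the units of the measured variable."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("SD must be non-negative")
        if self.n < 2:
            raise ValueError("need n >= 2")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False  # zero-variance input; t is a convention


def two_sample_t_from_summary(
    g1: SummaryStats, g2: SummaryStats, variant: str = "pooled"
) -> TTestResult:
    """Two-sample t-test from group summary statistics.

    ``pooled`` uses the equal-variance estimator
    sp^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2) with df = n1+n2-2;
    ``welch`` uses the unequal-variance form. Two-tailed p.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if g1.sd == 0 and g2.sd == 0:
        df = g1.n + g2.n - 2
        if g1.mean == g2.mean:
            return TTestResult(0.0, df, 1.0, degenerate=True)
        return TTestResult(float(np.inf) * np.sign(g1.mean - g2.mean), df, 0.0, degenerate=True)
    t, p = sp_stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = g1.n + g2.n - 2
    else:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return TTestResult(float(t), float(df), float(p))


def cohens_d_from_summary(g1: SummaryStats, g2: SummaryStats) -> float:
    """Cohen's d with average-variance pooling of the two condition SDs.

    d = (m2 - m1) / sqrt((s1^2 + s2^2) / 2). Chosen because it is the
    convention under which the reference behavioural effect sizes are
    reproduced; the paired d_z form is :func:`paired_t`'s ``d_z``.
    """
    pooled = np.sqrt((g1.sd**2 + g2.sd**2) / 2.0)
    if pooled == 0:
        raise ValueError("zero pooled SD: d undefined")
    return float((g2.mean - g1.mean) / pooled)


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[TTestResult, float]:
    """Paired t-test on ``y - x`` differences; returns (result, d_z).

    d_z = mean(diff) / SD(diff). Zero-variance differences are flagged
    (``degenerate=True``) with t = 0 or +/-inf by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length vectors with n >= 2")
    diff = y - x
    sd = diff.std(ddof=1)
    n = len(diff)
    scale = max(np.abs(diff).max(), 1.0)
    if sd <= 1e-12 * scale:  # constant differences up to float rounding
        m = diff.mean()
        t = 0.0 if m == 0 else float(np.inf) * np.sign(m)
        return TTestResult(t, n - 1, 1.0 if m == 0 else 0.0, degenerate=True), np.nan
    t, p = sp_stats.ttest_rel(y, x)
    d_z = diff.mean() / sd
    return TTestResult(float(t), n - 1, float(p)), float(d_z)


def bh_fdr(p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(significant_mask, adjusted_p)`` for the p-value vector at
    level ``q``. An empty input yields empty outputs.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a flat vector")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
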