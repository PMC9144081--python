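"""Validation and cohort statistics.

The device-validation side: repeatability (sample SD of repeated weighings)
and two-sample comparison against a reference scale (Welch t by default,
paired t for matched readings).  The cohort side: arch-type frequencies and
Pearson correlation / simple linear regression between posture variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, UsageError


@dataclass
class RepeatabilitySummary:
    """Sample mean and SD (n-1 denominator) of repeated measurements."""

    n: int
    mean: float
    sd: float


@dataclass
class ComparisonResult:
    """Two-sample t comparison with a 0.05 significance flag."""

    t_statistic: float
    df: float
    p_value: float
    significant_at_005: bool
    paired: bool


@dataclass
class AssociationResult:
    """Pearson r plus the OLS line of y on x."""

    pearson_r: float
    slope: float
    intercept: float
    n: int


def repeatability_sd(measurements) -> RepeatabilitySummary:
    """Repeatability of a measurement series as its sample SD."""
    x = np.asarray(measurements, dtype=float)
    if x.size < 2:
        raise UsageError("repeatability needs at least 2 measurements")
    if not np.isfinite(x).all():
        raise DataError("measurements contain non-finite values")
    return RepeatabilitySummary(n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)))


def two_sample_t(a, b, paired: bool = False) -> ComparisonResult:
    """Compare two measurement arms; Welch's t unless ``paired``.

    A paired comparison with zero variance of the differences has no defined
    t statistic and is reported as a degenerate-data error.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if paired:
        if x.size != y.size:
            raise UsageError("paired comparison needs equal-length arms")
        if x.size < 2:
            raise UsageError("paired comparison needs at least 2 pairs")
        d = x - y
        if np.ptp(d) == 0 and d.std() == 0:
            raise DataError("degenerate paired comparison: differences have zero variance")
        res = stats.ttest_rel(x, y)
        df = float(x.size - 1)
    else:
        if x.size < 2 or y.size < 2:
            raise UsageError("each arm needs at least 2 measurements")
        res = stats.ttest_ind(x, y, equal_var=False)
        df = float(res.df)
    return ComparisonResult(
        t_statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        significant_at_005=bool(res.pvalue < 0.05),
        paired=paired,
    )


def arch_frequencies(cohort: pd.DataFrame) -> dict[str, float]:
    """Percent frequency of each foot-arch type present in a cohort."""
    if len(cohort) == 0:
        raise UsageError("cohort is empty")
    if "arch_type" not in cohort.columns:
        raise DataError("cohort table has no arch_type column")
    counts = cohort["arch_type"].value_counts()
    return {str(k): float(100.0 * v / len(cohort)) for k, v in counts.items()}


def associate(x, y) -> AssociationResult:
    """Pearson correlation and OLS regression line of y on x."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise UsageError("x and y must have equal length")
    if xa.size < 3:
        raise UsageError("association needs at least 3 points")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise DataError("association inputs contain non-finite values")
    if np.ptp(xa) == 0:
        raise DataError("degenerate association: x is constant")
    fit = stats.linregress(xa, ya)
    return AssociationResult(
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(xa.size),
    )
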