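"""Group-comparison statistics for per-participant densities.

The comparison of a symptomatic and a control group uses: Levene's test for
equality of variances (classic centre=mean variant by default, with the
Brown-Forsythe median-centred variant selectable), the independent-samples
t-test assuming equal variances (pooled variance, df = n1 + n2 - 2),
pooled-SD Cohen's d, and Benjamini-Hochberg adjustment when several
densities are tested at once.

Both raw-vector and summary-statistic (n, mean, SD) input modes are
provided; the latter lets published group tables be checked directly.
Repeated measures within a participant are collapsed to a single
per-participant density before any of these tests — the supported analysis
path operates on participant means, not per-image values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "levene_test",
    "t_test_equal_var",
    "t_test_from_summary",
    "cohens_d_pooled",
    "cohens_d_from_summary",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class GroupComparison:
    """Two-group equal-variance t-test result with effect size."""

    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    levene_p: float | None
    t_stat: float
    df: int
    p_value: float
    cohens_d: float
    adjusted_p: float | None = None


def _check_groups(x: np.ndarray, y: np.ndarray) -> None:
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")


def levene_test(x: Sequence[float], y: Sequence[float],
                center: str = "mean") -> tuple[float, float]:
    """Levene's test for equality of variances; returns (statistic, p).

    ``center='mean'`` is the classic Levene test; ``center='median'`` the
    Brown-Forsythe variant.
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    _check_groups(xa, ya)
    centre_fn = np.mean if center == "mean" else np.median
    spreads = np.concatenate([np.abs(xa - centre_fn(xa)), np.abs(ya - centre_fn(ya))])
    if np.allclose(spreads, spreads[0]):
        # no spread variation at all (e.g. both groups constant): the F
        # statistic is 0/0; equality of variances is trivially not rejected
        return 0.0, 1.0
    stat, p = sps.levene(xa, ya, center=center)
    return float(stat), float(p)


def cohens_d_pooled(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with the pooled standard deviation.

    d = (mean1 - mean2) / s_p with
    s_p^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2).
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    _check_groups(xa, ya)
    return cohens_d_from_summary(
        xa.size, float(np.mean(xa)), float(np.std(xa, ddof=1)),
        ya.size, float(np.mean(ya)), float(np.std(ya, ddof=1)),
    )


def cohens_d_from_summary(n1: int, mean1: float, sd1: float,
                          n2: int, mean2: float, sd2: float) -> float:
    """Pooled-SD Cohen's d from group summary statistics."""
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var <= 0:
        raise ValueError("zero pooled standard deviation")
    return (mean1 - mean2) / float(np.sqrt(pooled_var))


def t_test_equal_var(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Independent-samples t-test assuming equal variances (two-sided).

    Pooled-variance t statistic with df = n1 + n2 - 2; Levene's test and
    pooled Cohen's d are computed alongside.
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    _check_groups(xa, ya)
    if np.std(xa, ddof=1) == 0 and np.std(ya, ddof=1) == 0:
        raise ValueError("degenerate input: both groups have zero variance")
    _, lev_p = levene_test(xa, ya)
    res = sps.ttest_ind(xa, ya, equal_var=True)
    return GroupComparison(
        n1=xa.size, n2=ya.size,
        mean1=float(np.mean(xa)), mean2=float(np.mean(ya)),
        sd1=float(np.std(xa, ddof=1)), sd2=float(np.std(ya, ddof=1)),
        levene_p=lev_p,
        t_stat=float(res.statistic),
        df=xa.size + ya.size - 2,
        p_value=float(res.pvalue),
        cohens_d=cohens_d_pooled(xa, ya),
    )


def t_test_from_summary(n1: int, mean1: float, sd1: float,
                        n2: int, mean2: float, sd2: float) -> GroupComparison:
    """Equal-variance t-test from group summary statistics (n, mean, SD).

    Lets printed group tables be checked without raw data; Levene's test
    needs raw observations and is reported as None.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return GroupComparison(
        n1=n1, n2=n2, mean1=mean1, mean2=mean2, sd1=sd1, sd2=sd2,
        levene_p=None,
        t_stat=float(res.statistic),
        df=n1 + n2 - 2,
        p_value=float(res.pvalue),
        cohens_d=cohens_d_from_summary(n1, mean1, sd1, n2, mean2, sd2),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
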