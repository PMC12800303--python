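"""Segmentation and method-agreement metrics.

Pixel-wise overlap metrics (Dice, recall, precision, specificity) for
comparing predicted and ground-truth masks; error metrics (MAPE, MAE) for
comparing estimated quantities to reference values; and paired-method
agreement statistics: Bland-Altman bias and 95% limits of agreement,
intraclass correlation (two-way, absolute agreement, with F-based
confidence intervals), and Pearson correlation with a Fisher-z interval.

Conventions fixed here (they matter for edge cases the formulas leave
open): comparing an empty prediction to an empty reference counts as
perfect agreement (Dice/recall/precision = 1); MAPE pairs with a zero
reference are excluded with a warning; limits of agreement use the 1.96
normal multiplier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PixelConfusion",
    "confusion",
    "dice",
    "recall",
    "precision",
    "specificity",
    "mape",
    "mae",
    "bland_altman",
    "icc",
    "pearson",
    "AgreementReport",
    "agreement_report",
]


@dataclass(frozen=True)
class PixelConfusion:
    """Pixel-level confusion counts between a predicted and a true mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_binary(mask) -> np.ndarray:
    data = mask.data if hasattr(mask, "data") else np.asarray(mask)
    return np.asarray(data).astype(bool)


def confusion(pred, truth) -> PixelConfusion:
    p, t = _as_binary(pred), _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return PixelConfusion(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def dice(pred, truth) -> float:
    """2*TP / (2*TP + FP + FN); 1.0 when both masks are empty."""
    c = confusion(pred, truth)
    denom = 2 * c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else 2.0 * c.tp / denom


def recall(pred, truth) -> float:
    """Sensitivity TP / (TP + FN); 1.0 when the reference is empty."""
    c = confusion(pred, truth)
    return 1.0 if c.tp + c.fn == 0 else c.tp / (c.tp + c.fn)


def precision(pred, truth) -> float:
    """TP / (TP + FP); 1.0 when the prediction is empty."""
    c = confusion(pred, truth)
    return 1.0 if c.tp + c.fp == 0 else c.tp / (c.tp + c.fp)


def specificity(pred, truth) -> float:
    """TN / (TN + FP); 1.0 when there are no true negatives to classify."""
    c = confusion(pred, truth)
    return 1.0 if c.tn + c.fp == 0 else c.tn / (c.tn + c.fp)


# ---------------------------------------------------------------------------
# Error metrics
# ---------------------------------------------------------------------------

def _paired(pred: Sequence[float], truth: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 1 or p.size < 1:
        raise ValueError("pred and truth must be equal-length 1-D vectors")
    return p, t


def mape(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent.

    Pairs with a zero reference value are excluded (with a warning): a
    relative error is undefined there, and the measurands this package
    reports (lengths, densities) are positive in practice.
    """
    p, t = _paired(pred, truth)
    nonzero = t != 0
    if not nonzero.all():
        warnings.warn(
            f"mape: excluding {int((~nonzero).sum())} pair(s) with zero reference",
            stacklevel=2,
        )
    if not nonzero.any():
        raise ValueError("mape undefined: all reference values are zero")
    return float(100.0 * np.mean(np.abs(p[nonzero] - t[nonzero]) / np.abs(t[nonzero])))


def mae(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Mean absolute error, in the measurand's units."""
    p, t = _paired(pred, truth)
    return float(np.mean(np.abs(p - t)))


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

def bland_altman(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float, float]:
    """Bland-Altman statistics of paired differences d = a - b.

    Returns (bias, sd_diff, loa_low, loa_high) with the 95% limits of
    agreement at bias +/- 1.96 * SD (sample SD, n-1 denominator).
    """
    x, y = _paired(a, b)
    if x.size < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def _icc_anova(table: np.ndarray) -> tuple[float, float, float]:
    """Mean squares (rows, columns, error) of the two-way rating table."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((table - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(
    a: Sequence[float],
    b: Sequence[float],
    form: str = "single",
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Two-way absolute-agreement ICC between two raters, with 95% CI.

    ``form='single'`` gives the single-rater ICC(A,1); ``form='average'``
    the average-measures ICC(A,k). Absolute agreement penalizes systematic
    offsets between the raters, unlike consistency forms. The confidence
    interval is the standard F-based one (McGraw & Wong); average-measures
    bounds are the Spearman-Brown transform of the single-rater bounds.
    """
    if form not in ("single", "average"):
        raise ValueError("form must be 'single' or 'average'")
    x, y = _paired(a, b)
    if x.size < 3:
        raise ValueError("icc requires at least 3 paired observations")
    table = np.column_stack([x, y])
    n, k = table.shape
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        if np.allclose(x, y):
            return 1.0, (1.0, 1.0)
        raise ValueError("icc undefined: zero total variance with unequal columns")
    if np.array_equal(x, y):
        return 1.0, (1.0, 1.0)
    msr, msc, mse = _icc_anova(table)

    icc1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # F-based CI for the single-rater form (McGraw & Wong 1996)
    fj = msc / mse if mse > 0 else np.inf
    denom_a = (n - 1) * k**2 * icc1**2 * fj**2 + (
        n * (1 + (k - 1) * icc1) - k * icc1
    ) ** 2
    num_a = (k - 1) * (n - 1) * (
        k * icc1 * fj + n * (1 + (k - 1) * icc1) - k * icc1
    ) ** 2
    v = num_a / denom_a if denom_a > 0 else (n - 1) * (k - 1)
    f_low = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    lower, upper = max(lower, -1.0), min(upper, 1.0)
    if form == "single":
        return float(icc1), (float(lower), float(upper))

    def spearman_brown(r: float) -> float:
        return k * r / (1 + (k - 1) * r)

    return float(spearman_brown(icc1)), (
        float(spearman_brown(lower)),
        float(spearman_brown(upper)),
    )


def pearson(a: Sequence[float], b: Sequence[float],
            alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Product-moment correlation with the Fisher-z 95% confidence interval.

    CI = tanh(atanh(r) +/- z_{1-alpha/2} / sqrt(n - 3)).
    """
    x, y = _paired(a, b)
    if x.size < 3:
        raise ValueError("pearson requires at least 3 pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    r = float(sps.pearsonr(x, y).statistic)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = sps.norm.ppf(1 - alpha / 2) / np.sqrt(x.size - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


@dataclass(frozen=True)
class AgreementReport:
    """Paired-method agreement between automated and manual measurements."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    icc: float
    icc_ci: tuple[float, float]
    icc_form: str
    pearson_r: float
    pearson_ci: tuple[float, float]
    mape: float
    mae: float
    n: int


def agreement_report(
    automated: Sequence[float],
    manual: Sequence[float],
    icc_form: str = "single",
) -> AgreementReport:
    """Full agreement panel: Bland-Altman, ICC, Pearson, MAPE, MAE.

    Differences are automated - manual, so a negative bias means the
    automated method underestimates.
    """
    auto, man = _paired(automated, manual)
    bias, sd, lo, hi = bland_altman(auto, man)
    icc_val, icc_ci = icc(auto, man, form=icc_form)
    r, r_ci = pearson(auto, man)
    return AgreementReport(
        bias=bias, sd_diff=sd, loa_low=lo, loa_high=hi,
        icc=icc_val, icc_ci=icc_ci, icc_form=icc_form,
        pearson_r=r, pearson_ci=r_ci,
        mape=mape(auto, man), mae=mae(auto, man),
        n=int(auto.size),
    )
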