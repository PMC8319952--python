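"""Evaluation statistics: MSE, R^2, the per-plan |actual - predicted|
delta, Pearson correlation and the two-sided paired t-test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def _pair(a, b):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(actual, predicted) -> float:
    """Mean squared error."""
    a, p = _pair(actual, predicted)
    if len(a) < 1:
        raise ValueError("need at least one pair")
    return float(np.mean((a - p) ** 2))


def r_squared(actual, predicted) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    Undefined (raises) when the actual values are constant.
    """
    a, p = _pair(actual, predicted)
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("undefined R^2: actual values are constant")
    return 1.0 - float(np.sum((a - p) ** 2)) / ss_tot


@dataclass
class DeltaSummary:
    """Per-plan delta = |actual - predicted| with mean and sample sd."""

    values: np.ndarray
    mean: float
    sd: float


def delta_stat(actual_ratios, predicted_ratios) -> DeltaSummary:
    """Elementwise |actual - predicted| with its mean and sample sd."""
    a, p = _pair(actual_ratios, predicted_ratios)
    d = np.abs(a - p)
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return DeltaSummary(values=d, mean=float(d.mean()), sd=sd)


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value (t-transform,
    n-2 degrees of freedom)."""
    x, y = _pair(x, y)
    if len(x) < 3:
        raise ValueError("need at least three pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t-test, t = mean(d) / (sd(d)/sqrt(n)) on n-1 df.

    Identical inputs give (t=0, p=1); zero-variance nonzero differences
    have no finite t and raise.
    """
    a, b = _pair(a, b)
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
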