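"""Rater-agreement and method-comparison statistics.

Implements the verification statistics used to qualify kinematic
measurements: single-measures intraclass correlation (two-way random-effects
absolute agreement, ICC(2,1), or two-way mixed consistency, ICC(3,1)) with
F-based 95% confidence intervals and the conventional category labels;
Pearson correlation with a two-sided t-test; and Bland-Altman bias with 95%
limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ReliabilityResult",
    "BlandAltmanResult",
    "icc",
    "classify_icc",
    "pearson",
    "bland_altman",
    "ICC_MODELS",
]

ICC_MODELS = ("two_way_random_absolute", "two_way_mixed_consistency")

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str
    category: str
    n_subjects: int
    n_raters: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    means: np.ndarray
    diffs: np.ndarray


def classify_icc(value: float) -> str:
    """Conventional reliability category for an ICC value.

    > 0.75 excellent; [0.60, 0.75] good; [0.40, 0.60) moderate; < 0.40 poor.
    The 0.75 boundary goes to good (excellence requires strictly greater).
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"ICC must lie in [-1, 1], got {value}")
    if value > 0.75:
        return "excellent"
    if value >= 0.60:
        return "good"
    if value >= 0.40:
        return "moderate"
    return "poor"


def _mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows = subjects, columns = raters)."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(
    table: np.ndarray, model: str = "two_way_random_absolute", alpha: float = 0.05
) -> ReliabilityResult:
    """Single-measures intraclass correlation with an F-based CI.

    *table* is subjects x raters with no missing cells.  Models:

    * ``two_way_random_absolute`` — ICC(2,1): raters are a random sample,
      absolute agreement; CI by the Shrout-Fleiss / McGraw-Wong formulas
      with Satterthwaite degrees of freedom.
    * ``two_way_mixed_consistency`` — ICC(3,1): fixed raters, consistency;
      CI from F = MSR/MSE directly.
    """
    if model not in ICC_MODELS:
        raise ValueError(f"model must be one of {ICC_MODELS}, got {model!r}")
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("ratings table must be 2-D (subjects x raters)")
    if np.isnan(table).any():
        raise ValueError("ratings table must have no missing cells")
    n, k = table.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")
    if np.allclose(table, table.flat[0]):
        raise ValueError("degenerate ratings: zero total variance")

    msr, msc, mse = _mean_squares(table)

    if model == "two_way_mixed_consistency":
        value = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:  # perfect consistency: F is infinite, CI collapses at 1
            lo = hi = value
        else:
            f_obs = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (f_l - 1) / (f_l + k - 1)
            hi = (f_u - 1) / (f_u + k - 1)
    else:  # ICC(2,1)
        value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        # Satterthwaite df for the denominator of the CI F statistics;
        # clip the estimate away from 1 to keep a, b finite in the exact-
        # agreement limit (the CI then collapses onto the estimate)
        v_clip = min(value, 1.0 - 1e-12)
        a = (k * v_clip) / (n * (1 - v_clip))
        b = 1 + (k * v_clip * (n - 1)) / (n * (1 - v_clip))
        denom = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = (a * msc + b * mse) ** 2 / denom if denom > 0 else (n - 1) * (k - 1)
        f_star_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_star_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_star_l * mse) / (
            f_star_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_star_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_star_u * msr
        )

    lo = min(lo, value)
    hi = max(hi, value)
    return ReliabilityResult(
        icc=float(value),
        ci_low=float(lo),
        ci_high=float(hi),
        model=model,
        category=classify_icc(float(np.clip(value, -1.0, 1.0))),
        n_subjects=n,
        n_raters=k,
    )


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 pairs, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bland_altman(measured: np.ndarray, reference: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement: bias and 95% limits of agreement.

    d_i = measured_i - reference_i; bias = mean(d); limits = bias +/- 1.96 sd(d)
    with the n-1 denominator.  The per-pair (mean, difference) arrays are kept
    for plotting.
    """
    measured = np.asarray(measured, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if measured.shape != reference.shape or measured.ndim != 1:
        raise ValueError("series must be 1-D of equal length")
    if measured.size < 2:
        raise ValueError(f"need >= 2 pairs, got {measured.size}")
    diffs = measured - reference
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        sd_diff=sd,
        means=(measured + reference) / 2.0,
        diffs=diffs,
    )
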