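"""Inter-reader agreement: intraclass correlation and Gwet's AC1.

Multiple readers independently measure every knee, so continuous
measurements are analysed with the two-way random-effects, absolute
agreement, single-measures intraclass correlation — ICC(2,1) in the
Shrout & Fleiss taxonomy: readers are a random sample and systematic
reader offsets count against agreement. Consistency and average-measure
variants are available through ``model``.

Categorical shape judgments (concave / flat / convex) are analysed with
Gwet's AC1, a chance-corrected agreement coefficient whose chance term
stays stable under prevalence imbalance (unlike Cohen/Fleiss kappa, which
collapses when one category dominates — here most control trochleae are
concave). The AC1 confidence interval uses a subject-level jackknife.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["AgreementResult", "icc", "gwet_ac1"]


@dataclass(frozen=True)
class AgreementResult:
    """A coefficient with its 95% confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    method: str
    n_subjects: int
    n_raters: int


def _as_grid(ratings, dtype=float) -> np.ndarray:
    grid = np.asarray(ratings, dtype=dtype)
    if grid.ndim != 2 or grid.shape[0] < 2 or grid.shape[1] < 2:
        raise ValueError("ratings must be a subjects x raters grid, >= 2 each")
    return grid


def _anova_mean_squares(grid: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x raters) ANOVA mean squares: rows, columns, error."""
    n, k = grid.shape
    grand = grid.mean()
    row_means = grid.mean(axis=1)
    col_means = grid.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((grid - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    return (
        ss_rows / (n - 1),
        ss_cols / (k - 1),
        ss_err / ((n - 1) * (k - 1)),
    )


def icc(
    ratings,
    model: str = "two_way_random_absolute_single",
    confidence: float = 0.95,
) -> AgreementResult:
    """Intraclass correlation for a complete subjects x raters grid.

    ``model`` selects among the two-way random variants:
    ``two_way_random_absolute_single`` (default, ICC(2,1)),
    ``two_way_random_absolute_average`` (ICC(2,k)) and
    ``two_way_random_consistency_single`` (ICC(3,1)-style consistency).
    The default CI is the standard F-based interval for ICC(2,1)
    (Shrout & Fleiss); consistency/average variants use their F intervals.
    """
    grid = _as_grid(ratings)
    if np.isnan(grid).any():
        grid = grid[~np.isnan(grid).any(axis=1)]  # complete-case deletion
        if grid.shape[0] < 2:
            raise ValueError("fewer than 2 complete cases")
    n, k = grid.shape
    msr, msc, mse = _anova_mean_squares(grid)
    alpha = 1.0 - confidence

    if np.allclose(grid, grid[0, 0]):
        warnings.warn("constant ratings grid: ICC undefined, reporting 1", stacklevel=2)
        return AgreementResult(1.0, math.nan, math.nan, model, n, k)

    if model == "two_way_random_absolute_single":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        est = (msr - mse) / denom
        # Shrout & Fleiss (1979) F-based interval with Satterthwaite df
        fj = msc / mse if mse > 0 else math.inf
        a_ = (k * est) / (n * (1 - est)) if est < 1 else math.inf
        b_ = 1 + (k * est * (n - 1)) / (n * (1 - est)) if est < 1 else math.inf
        if math.isfinite(a_) and math.isfinite(fj):
            v_num = (a_ * fj + b_) ** 2
            v_den = (a_**2 * fj**2) / (k - 1) + b_**2 / ((n - 1) * (k - 1))
            v = v_num / v_den
            f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
        else:
            lo = hi = math.nan
    elif model == "two_way_random_absolute_average":
        denom = msr + (msc - mse) / n
        est = (msr - mse) / denom
        single = icc(grid, "two_way_random_absolute_single", confidence)
        lo = single.ci_low * k / (1 + (k - 1) * single.ci_low)
        hi = single.ci_high * k / (1 + (k - 1) * single.ci_high)
    elif model == "two_way_random_consistency_single":
        est = (msr - mse) / (msr + (k - 1) * mse)
        f_obs = msr / mse
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        lo = (f_l - 1) / (f_l + k - 1)
        hi = (f_u - 1) / (f_u + k - 1)
    else:
        raise ValueError(f"unknown ICC model {model!r}")

    return AgreementResult(float(est), float(lo), float(hi), model, n, k)


def _ac1_point(grid: np.ndarray, categories: Sequence) -> float:
    n, k = grid.shape
    q = len(categories)
    counts = np.stack([(grid == c).sum(axis=1) for c in categories], axis=1)
    # per-subject observed agreement among the k*(k-1) ordered rater pairs
    pa = float(np.mean((counts * (counts - 1)).sum(axis=1) / (k * (k - 1))))
    pi = counts.mean(axis=0) / k
    pe = float(np.sum(pi * (1 - pi)) / (q - 1))
    if pe >= 1.0:
        return 1.0
    return (pa - pe) / (1 - pe)


def gwet_ac1(
    ratings,
    categories: Optional[Sequence] = None,
    confidence: float = 0.95,
) -> AgreementResult:
    """Gwet's AC1 for a complete subjects x raters grid of nominal labels.

    ``categories`` declares the label set (defaults to the labels observed);
    the CI is a subject-level jackknife normal interval, truncated to
    [-1, 1].
    """
    grid = _as_grid(ratings, dtype=object)
    n, k = grid.shape
    if categories is None:
        categories = sorted({str(v) for v in grid.ravel()})
    else:
        categories = [str(c) for c in categories]
    grid = np.vectorize(str)(grid)
    unknown = set(grid.ravel()) - set(categories)
    if unknown:
        raise ValueError(f"ratings outside the declared label set: {sorted(unknown)}")
    if len(categories) < 2:
        warnings.warn(
            "single-category label set: chance agreement degenerate, reporting 1",
            stacklevel=2,
        )
        return AgreementResult(1.0, math.nan, math.nan, "gwet_ac1", n, k)

    est = _ac1_point(grid, categories)
    if len(set(grid.ravel())) == 1:
        warnings.warn("all ratings identical: AC1 reported as 1", stacklevel=2)
        return AgreementResult(1.0, math.nan, math.nan, "gwet_ac1", n, k)

    # subject-level jackknife
    jack = np.array(
        [_ac1_point(np.delete(grid, i, axis=0), categories) for i in range(n)]
    )
    se = math.sqrt((n - 1) / n * np.sum((jack - jack.mean()) ** 2))
    z = stats.norm.ppf(0.5 + confidence / 2)
    lo, hi = max(-1.0, est - z * se), min(1.0, est + z * se)
    return AgreementResult(float(est), float(lo), float(hi), "gwet_ac1", n, k)
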