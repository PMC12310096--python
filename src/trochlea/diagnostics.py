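"""Diagnostic performance and comparative statistics.

Covers the evaluation layer of the classification study: confusion matrices
and sensitivity/specificity for each Option criterion, odds ratios with
Woolf (log-scale) confidence intervals for trochlear-shape exposure,
two-sample mean differences with pooled-t confidence intervals, and the
a-priori sample-size calculation via the exact noncentral-t power function
(the method G*Power uses; a normal approximation would understate the
required n by one in both published scenarios).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import ClassificationConfig, classify_option
from .geometry import KneeRecord, round_half_away

__all__ = [
    "ConfusionMatrix",
    "TwoByTwo",
    "PowerSpec",
    "confusion",
    "sens_spec",
    "odds_ratio",
    "mean_difference",
    "power_two_sample_t",
    "required_sample_size",
    "evaluate_options",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a binary test against case status."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure x case-status table: a=exposed cases, b=exposed controls,
    c=unexposed cases, d=unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")


@dataclass(frozen=True)
class PowerSpec:
    """Design of a one-sided two-sample t test power analysis."""

    effect_size_d: float
    alpha_one_sided: float = 0.025
    target_power: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.alpha_one_sided < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        if not 0.5 < self.target_power < 1:
            raise ValueError("target power must lie in (0.5, 1)")
        if self.effect_size_d <= 0:
            raise ValueError("effect size d must be positive")


def confusion(predictions: Sequence[bool], truth: Sequence[bool]) -> ConfusionMatrix:
    """Tabulate a boolean test against boolean case status."""
    pred = np.asarray(predictions, dtype=bool)
    y = np.asarray(truth, dtype=bool)
    if pred.shape != y.shape:
        raise ValueError("predictions and truth must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


def sens_spec(cm: ConfusionMatrix) -> tuple[int, int]:
    """Sensitivity and specificity as integer-rounded percentages."""
    if cm.n_cases == 0 or cm.n_controls == 0:
        raise ZeroDivisionError("sensitivity/specificity undefined on an empty margin")
    return (
        round_half_away(100.0 * cm.tp / cm.n_cases),
        round_half_away(100.0 * cm.tn / cm.n_controls),
    )


def odds_ratio(
    t: TwoByTwo, continuity: bool = False
) -> tuple[float, tuple[float, float]]:
    """Odds ratio (a*d)/(b*c) with a Woolf log-scale 95% CI.

    With a zero cell the OR is 0 or inf; pass ``continuity=True`` to add
    0.5 to every cell (Haldane-Anscombe) for a finite estimate and CI.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if continuity or 0 in (a, b, c, d):
        if not continuity:
            if b * c == 0 and a * d == 0:
                raise ValueError("odds ratio undefined: zero in both diagonals")
            orr = math.inf if b * c == 0 else 0.0
            return orr, (math.nan, math.nan)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    lo, hi = math.exp(math.log(orr) - z * se), math.exp(math.log(orr) + z * se)
    return orr, (lo, hi)


def format_or(value: float) -> str:
    """One-decimal reporting, two decimals below 1 (table style)."""
    return f"{value:.2f}" if value < 1 else f"{value:.1f}"


def mean_difference(
    group1: Sequence[float] | float,
    group2: Sequence[float] | float,
    confidence: float = 0.95,
) -> tuple[float, Optional[tuple[float, float]]]:
    """Difference of group means (group1 - group2) with a pooled-variance
    two-sample t confidence interval.

    Scalars are treated as known group means: the point estimate is
    returned with ``None`` in place of the CI.
    """
    if np.isscalar(group1) and np.isscalar(group2):
        return float(group1) - float(group2), None
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group for a confidence interval")
    diff = float(x.mean() - y.mean())
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    tcrit = stats.t.ppf(0.5 + confidence / 2, n1 + n2 - 2)
    return diff, (diff - tcrit * se, diff + tcrit * se)


def power_two_sample_t(n_per_group: int, d: float, alpha_one_sided: float) -> float:
    """Exact power of a one-sided two-sample t test with n per group.

    Under the alternative the test statistic is noncentral t with
    df = 2n - 2 and noncentrality d * sqrt(n/2); power is the probability
    it exceeds the central-t critical value.
    """
    df = 2 * n_per_group - 2
    nc = d * math.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha_one_sided, df)
    return float(stats.nct.sf(tcrit, df, nc))


def required_sample_size(spec: PowerSpec, n_max: int = 100_000) -> tuple[int, int]:
    """Smallest per-group n reaching the target power; returns (n, 2n)."""
    for n in range(2, n_max + 1):
        if power_two_sample_t(n, spec.effect_size_d, spec.alpha_one_sided) >= spec.target_power:
            return n, 2 * n
    raise ValueError(f"target power not attainable with n <= {n_max} per group")


OPTION_LABELS = {
    1: "sulcus angle >= cut",
    2: "LTI < cut",
    3: "sulcus angle >= cut AND LTI < cut",
    4: "sulcus angle >= cut OR LTI < cut",
}


def evaluate_options(
    records: Iterable[KneeRecord],
    cfg: ClassificationConfig = ClassificationConfig(),
) -> pd.DataFrame:
    """Sensitivity/specificity report of the four Option criteria.

    One row per option with TP/FP/TN/FN and integer-percent sensitivity
    and specificity; ``max_sensitivity`` marks the retained criterion
    (ties all marked).
    """
    records = list(records)
    truth = [r.group == "OPI" for r in records]
    if all(truth) or not any(truth):
        raise ValueError("need both OPI and control knees to evaluate criteria")
    rows = []
    for option in (1, 2, 3, 4):
        cm = confusion([classify_option(r, option, cfg) for r in records], truth)
        sens, spec = sens_spec(cm)
        rows.append(
            {
                "option": option,
                "criterion": OPTION_LABELS[option],
                "tp": cm.tp,
                "fp": cm.fp,
                "tn": cm.tn,
                "fn": cm.fn,
                "sensitivity_pct": sens,
                "specificity_pct": spec,
            }
        )
    report = pd.DataFrame(rows).set_index("option")
    report["max_sensitivity"] = (
        report["sensitivity_pct"] == report["sensitivity_pct"].max()
    )
    return report
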