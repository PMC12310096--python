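"""Single-split recursive-partitioning thresholds (CART with one node).

Each diagnostic cutpoint is derived independently per parameter by an
exhaustive search over candidate splits of the form ``value >= c``, where
``c`` ranges over the observed unique values, minimizing the weighted Gini
impurity of the two children. The published analysis reports exactly one
cutpoint per parameter, so no tree is grown beyond the root split and no
pruning or complexity parameter is involved.

Knees whose value is unmeasurable (convex trochleae, for the sulcus angle
and LTI) are excluded from the fit: a threshold on a value that does not
exist is undefined. The classifier handles those knees through its explicit
unmeasurability clauses instead. The number excluded is reported on the
rule so the exclusion is never silent.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .geometry import KneeRecord

__all__ = [
    "NoSplitError",
    "ThresholdRule",
    "gini",
    "best_split",
    "derive_thresholds",
    "SingleSplitClassifier",
    "DejourClassifier",
]

#: parameters thresholded in the published analysis, in report order
DEFAULT_PARAMETERS = ("sulcus_angle", "lti", "bump")


class NoSplitError(ValueError):
    """No informative split exists (single class or constant values)."""


@dataclass(frozen=True)
class ThresholdRule:
    """A one-parameter dysplasia criterion: ``parameter direction cutpoint``.

    ``direction`` is ``"ge"`` when values at or above the cutpoint are
    case-enriched (sulcus angle, bump) and ``"lt"`` when values below it
    are (LTI). ``uninformative`` marks a degenerate split whose impurity
    decrease is (near) zero.
    """

    parameter: str
    direction: str  # {"ge", "lt"}
    cutpoint: float
    impurity_decrease: float
    n_used: int = 0
    n_excluded_unmeasurable: int = 0
    uninformative: bool = False

    def is_positive(self, value: float) -> bool:
        """Does ``value`` satisfy the dysplastic side of the rule?"""
        return value >= self.cutpoint if self.direction == "ge" else value < self.cutpoint

    def to_dict(self) -> dict:
        return asdict(self)


def gini(counts: Sequence[float]) -> float:
    """Gini impurity 1 - sum(p_k^2) of a class-count vector."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("at least one class count must be positive")
    p = counts / total
    return float(1.0 - np.sum(p**2))


def best_split(
    values: Sequence[float],
    labels: Sequence[bool],
    parameter: str = "value",
    impurity: str = "gini",
) -> ThresholdRule:
    """Exhaustive search for the impurity-minimizing binary split.

    ``labels`` are True for cases (OPI). Candidates are rules
    ``value >= c`` for every observed unique value ``c`` that leaves both
    children nonempty; ties are broken toward the smallest cutpoint.
    ``impurity`` is ``"gini"`` (CART default) or ``"entropy"``.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D sequences")
    if np.any(np.isnan(v)):
        raise ValueError("unmeasurable entries must be excluded before splitting")
    if y.all() or (~y).all():
        raise NoSplitError("both classes must be present to derive a threshold")
    uniq = np.unique(v)
    if uniq.size < 2:
        raise NoSplitError("need at least two distinct values to split")

    if impurity == "gini":
        node_impurity = lambda pos, n: gini((n - pos, pos))
    elif impurity == "entropy":
        def node_impurity(pos: float, n: float) -> float:
            p = np.array([pos, n - pos]) / n
            p = p[p > 0]
            return float(-(p * np.log2(p)).sum())
    else:
        raise ValueError(f"unknown impurity {impurity!r}")

    n = v.size
    parent = node_impurity(y.sum(), n)
    best = None  # (weighted_impurity, cutpoint, right_pos, n_right)
    for c in uniq[1:]:  # splitting at the minimum leaves the left child empty
        right = v >= c
        n_right = int(right.sum())
        pos_right = int(y[right].sum())
        pos_left = int(y.sum()) - pos_right
        w = (
            (n - n_right) / n * node_impurity(pos_left, n - n_right)
            + n_right / n * node_impurity(pos_right, n_right)
        )
        if best is None or w < best[0] - 1e-12:
            best = (w, float(c), pos_right, n_right)
    assert best is not None
    w, cut, pos_right, n_right = best
    decrease = parent - w
    # the ">= c" side is dysplastic when it is case-enriched
    rate_right = pos_right / n_right
    rate_left = (y.sum() - pos_right) / (n - n_right)
    direction = "ge" if rate_right >= rate_left else "lt"
    return ThresholdRule(
        parameter=parameter,
        direction=direction,
        cutpoint=cut,
        impurity_decrease=float(decrease),
        n_used=int(n),
        uninformative=decrease <= 1e-9,
    )


def _extract(records: Sequence[KneeRecord], parameter: str) -> tuple[np.ndarray, np.ndarray, int]:
    vals, labs, excluded = [], [], 0
    for r in records:
        if r.group not in ("OPI", "control"):
            raise ValueError(f"knee {r.knee_id!r} has no group label")
        value = getattr(r, parameter)
        if value is None:
            excluded += 1
            continue
        vals.append(float(value))
        labs.append(r.group == "OPI")
    return np.asarray(vals), np.asarray(labs, dtype=bool), excluded


def derive_thresholds(
    records: Sequence[KneeRecord],
    parameters: Sequence[str] = DEFAULT_PARAMETERS,
    impurity: str = "gini",
) -> dict[str, ThresholdRule]:
    """Fit one single-split rule per parameter on a labeled cohort.

    Unmeasurable values are dropped per parameter (count recorded on the
    rule); each parameter is fit independently.
    """
    rules: dict[str, ThresholdRule] = {}
    for p in parameters:
        vals, labs, excluded = _extract(records, p)
        rule = best_split(vals, labs, parameter=p, impurity=impurity)
        rules[p] = ThresholdRule(
            **{**rule.to_dict(), "n_excluded_unmeasurable": excluded}
        )
    return rules


class SingleSplitClassifier(ClassifierMixin, BaseEstimator):
    """Depth-one CART classifier: a single impurity-optimal cutpoint.

    Fits a rule ``x >= cutpoint_`` (or ``x < cutpoint_``, whichever side is
    case-enriched) on a single feature by exhaustive Gini (or entropy)
    search. ``predict`` returns booleans (True = case).

    Parameters
    ----------
    impurity : {"gini", "entropy"}
        Split quality criterion.

    Attributes
    ----------
    cutpoint_ : float
        Selected threshold, the smallest observed value among ties.
    direction_ : {"ge", "lt"}
        Which side of the cutpoint is predicted positive.
    impurity_decrease_ : float
        Parent impurity minus weighted child impurity.
    rule_ : ThresholdRule
        The fitted rule as a frozen record.
    """

    def __init__(self, impurity: str = "gini"):
        self.impurity = impurity

    def fit(self, X, y, parameter: str = "value"):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("SingleSplitClassifier handles exactly one feature")
            X = X[:, 0]
        y = np.asarray(y, dtype=bool)
        self.rule_ = best_split(X, y, parameter=parameter, impurity=self.impurity)
        self.cutpoint_ = self.rule_.cutpoint
        self.direction_ = self.rule_.direction
        self.impurity_decrease_ = self.rule_.impurity_decrease
        self.classes_ = np.array([False, True])
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "rule_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return np.array([self.rule_.is_positive(x) for x in X])


class DejourClassifier(BaseEstimator):
    """Dysplasia typing with published or data-derived cutpoints.

    With ``refit_cutpoints=False`` (default) the published cutpoints
    (157 deg / 14 deg / 5 mm) are used and ``fit`` only validates the
    input. With ``refit_cutpoints=True``, ``fit`` re-derives all three
    cutpoints from the labeled cohort by single-split partitioning.

    ``predict`` returns the Type 0-3 grade per knee; ``predict_dysplastic``
    applies one of the four Option screening criteria (default Option 4,
    the published choice).
    """

    def __init__(
        self,
        sulcus_cut: int = 157,
        lti_cut: int = 14,
        bump_cut: int = 5,
        bump_plane: str = "sagittal",
        option: int = 4,
        refit_cutpoints: bool = False,
        impurity: str = "gini",
    ):
        self.sulcus_cut = sulcus_cut
        self.lti_cut = lti_cut
        self.bump_cut = bump_cut
        self.bump_plane = bump_plane
        self.option = option
        self.refit_cutpoints = refit_cutpoints
        self.impurity = impurity

    def _records(self, X) -> list[KneeRecord]:
        if isinstance(X, (list, tuple)) and all(isinstance(r, KneeRecord) for r in X):
            return list(X)
        from .io import records_from_frame  # local import to avoid a cycle

        return records_from_frame(X)

    def fit(self, X, y=None):
        records = self._records(X)
        if self.refit_cutpoints:
            if y is not None:
                records = [
                    KneeRecord(**{**_record_fields(r), "group": "OPI" if lab else "control"})
                    for r, lab in zip(records, y)
                ]
            rules = derive_thresholds(records, impurity=self.impurity)
            self.sulcus_cut_ = rules["sulcus_angle"].cutpoint
            self.lti_cut_ = rules["lti"].cutpoint
            self.bump_cut_ = rules["bump"].cutpoint
            self.rules_ = rules
        else:
            self.sulcus_cut_ = float(self.sulcus_cut)
            self.lti_cut_ = float(self.lti_cut)
            self.bump_cut_ = float(self.bump_cut)
        return self

    def _config(self):
        from .classification import ClassificationConfig

        check_is_fitted(self, "sulcus_cut_")
        return ClassificationConfig(
            sulcus_cut=self.sulcus_cut_,
            lti_cut=self.lti_cut_,
            bump_cut=self.bump_cut_,
            bump_plane=self.bump_plane,
        )

    def predict(self, X):
        """Type 0-3 per knee."""
        from .classification import classify_v3

        cfg = self._config()
        return np.array([classify_v3(r, cfg) for r in self._records(X)])

    def predict_dysplastic(self, X, option: Optional[int] = None):
        """Boolean screening result per knee under one Option criterion."""
        from .classification import classify_option

        cfg = self._config()
        opt = self.option if option is None else option
        return np.array([classify_option(r, opt, cfg) for r in self._records(X)])


def _record_fields(r: KneeRecord) -> dict:
    return {
        "knee_id": r.knee_id,
        "group": r.group,
        "shape": r.shape,
        "sulcus_angle": r.sulcus_angle,
        "lti": r.lti,
        "cto": r.cto,
        "bump": r.bump,
        "bump_axial": r.bump_axial,
        "dysplasia_type": r.dysplasia_type,
    }
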