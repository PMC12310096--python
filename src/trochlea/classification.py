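"""Dejour v3.0 trochlear dysplasia typing and the Option diagnostic criteria.

The published rule grades each knee from three quantities — sulcus angle,
lateral trochlear inclination (LTI) and sagittal central bump — with fixed
cutpoints (157 deg, 14 deg, 5 mm):

* Type 0 (no dysplasia):       sulcus < 157 AND LTI >= 14 (both measurable)
* Type 1 (low grade):          (sulcus >= 157 OR LTI < 14) AND bump < 5
* Type 2 (moderate grade):     (sulcus OR LTI unmeasurable) AND bump < 5
* Type 3 (high grade):         (sulcus >= 157 OR unmeasurable OR LTI < 14
                                OR unmeasurable) AND bump >= 5

The four clauses are mutually exclusive and exhaustive; ``classify_v3``
implements them in an equivalent nested form. Note that Type 0 ignores the
bump: a knee with a normal sulcus and LTI but a bump >= 5 mm is Type 0 and
is flagged rather than reclassified.

The four Option criteria for dysplasia screening are single-threshold or
combined tests on the sulcus angle and LTI. Unmeasurable (convex) values
count as satisfying their clause — a convex trochlea is maximally
dysplastic for both quantities.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence
import warnings

import pandas as pd

from .geometry import KneeRecord

__all__ = [
    "ClassificationConfig",
    "IncompleteRecordError",
    "classify_v3",
    "classify_option",
    "summarize_types",
]


class IncompleteRecordError(ValueError):
    """A record lacks a value required by the classification rule."""


@dataclass(frozen=True)
class ClassificationConfig:
    """Cutpoints of the classification rule (published defaults)."""

    sulcus_cut: int = 157  # degrees; dysplastic at or above
    lti_cut: int = 14  # degrees; dysplastic below
    bump_cut: int = 5  # mm; high grade at or above
    bump_plane: str = "sagittal"  # which bump drives classification

    def __post_init__(self) -> None:
        if min(self.sulcus_cut, self.lti_cut, self.bump_cut) <= 0:
            raise ValueError("all cutpoints must be positive")
        if self.bump_plane not in ("sagittal", "axial"):
            raise ValueError("bump_plane must be 'sagittal' or 'axial'")


def _bump_of(record: KneeRecord, cfg: ClassificationConfig) -> int:
    bump = record.bump if cfg.bump_plane == "sagittal" else record.bump_axial
    if bump is None:
        raise IncompleteRecordError(
            f"knee {record.knee_id!r}: missing {cfg.bump_plane} bump"
        )
    return bump


def classify_v3(
    record: KneeRecord, cfg: ClassificationConfig = ClassificationConfig()
) -> int:
    """Assign the Type 0–3 dysplasia grade to one knee.

    Mutates nothing; returns the type. Knees that are Type 0 despite a bump
    at or above the cut exist and are valid — callers wanting the warning
    flag should use :func:`assign_types`.
    """
    sa, lti = record.sulcus_angle, record.lti
    bump = _bump_of(record, cfg)
    measurable = sa is not None and lti is not None
    if measurable and sa < cfg.sulcus_cut and lti >= cfg.lti_cut:
        return 0
    if bump >= cfg.bump_cut:
        return 3
    if not measurable:
        return 2
    return 1


def assign_types(
    records: Iterable[KneeRecord], cfg: ClassificationConfig = ClassificationConfig()
) -> list[KneeRecord]:
    """Classify every record in place (sets ``dysplasia_type`` and flags)."""
    records = list(records)
    for r in records:
        r.dysplasia_type = classify_v3(r, cfg)
        if r.dysplasia_type == 0 and _bump_of(r, cfg) >= cfg.bump_cut:
            if "type0_with_bump" not in r.flags:
                r.flags.append("type0_with_bump")
    return records


def classify_option(
    record: KneeRecord,
    option: int,
    cfg: ClassificationConfig = ClassificationConfig(),
) -> bool:
    """Evaluate one of the four dysplasia screening criteria.

    Option 1: sulcus >= cut; Option 2: LTI < cut; Option 3: both;
    Option 4: either. Unmeasurable values satisfy their clause.
    """
    if option not in (1, 2, 3, 4):
        raise ValueError(f"option must be 1..4, got {option}")
    sulcus_pos = record.sulcus_angle is None or record.sulcus_angle >= cfg.sulcus_cut
    lti_pos = record.lti is None or record.lti < cfg.lti_cut
    if option == 1:
        return sulcus_pos
    if option == 2:
        return lti_pos
    if option == 3:
        return sulcus_pos and lti_pos
    return sulcus_pos or lti_pos


def summarize_types(records: Sequence[KneeRecord]) -> pd.DataFrame:
    """Per-type counts and within-type OPI prevalence.

    Returns a frame indexed by dysplasia type with columns ``n``, ``n_opi``,
    ``n_control`` and ``opi_prevalence_pct`` (one-decimal percent).
    Records without an assigned type are excluded with a warning.
    """
    records = list(records)
    untyped = [r for r in records if r.dysplasia_type is None]
    if untyped:
        warnings.warn(
            f"excluding {len(untyped)} unclassified record(s) from the type summary",
            stacklevel=2,
        )
    typed = [r for r in records if r.dysplasia_type is not None]
    counts: Counter = Counter()
    opi: Counter = Counter()
    for r in typed:
        counts[r.dysplasia_type] += 1
        if r.group == "OPI":
            opi[r.dysplasia_type] += 1
    rows = []
    for t in sorted(counts):
        n, n_opi = counts[t], opi[t]
        rows.append(
            {
                "dysplasia_type": t,
                "n": n,
                "n_opi": n_opi,
                "n_control": n - n_opi,
                "opi_prevalence_pct": round(100.0 * n_opi / n, 1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["dysplasia_type", "n", "n_opi", "n_control", "opi_prevalence_pct"],
    ).set_index("dysplasia_type")
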