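"""CSV interchange for measurement records and landmark tables.

Measurements travel as one row per knee with the token ``NA`` for
unmeasurable sulcus angle / LTI (never a numeric sentinel). Landmark tables
are long-format: one row per digitized point per knee, with the plane and
point name declared per row and the trochlear shape in a per-knee column.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import pandas as pd

from .geometry import (
    AxialLandmarks,
    InvalidLandmarksError,
    KneeRecord,
    PlanePoint,
    SagittalLandmarks,
)

__all__ = [
    "MEASUREMENT_COLUMNS",
    "read_measurements",
    "write_measurements",
    "records_from_frame",
    "frame_from_records",
    "read_landmarks",
]

MEASUREMENT_COLUMNS = [
    "knee_id",
    "group",
    "shape",
    "sulcus_angle",
    "lti",
    "cto",
    "bump_axial",
    "bump_sagittal",
]

_NA = "NA"

#: landmark point names and the plane each belongs to
_POINT_PLANES = {
    "TGC": "axial",
    "LTC": "axial",
    "MTC": "axial",
    "POST_MED": "axial",
    "POST_LAT": "axial",
    "L": "cranial_axial",
    "M": "cranial_axial",
    "ACT": "cranial_axial",
    "AFCL1": "sagittal",
    "AFCL2": "sagittal",
    "APEX": "sagittal",
}


def _opt_int(value, row: int, column: str) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        if value.strip().upper() in (_NA, "NAN", ""):
            return None
        value = value.strip()
    try:
        return int(round(float(value)))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"row {row}: column {column!r} has non-numeric value {value!r}") from exc


def records_from_frame(frame: pd.DataFrame) -> list[KneeRecord]:
    """Build validated knee records from a measurements table."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns and c != "group"]
    if missing:
        raise ValueError(f"measurements table is missing columns: {missing}")
    records = []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        raw_flags = row.get("flags")
        flags = (
            [f for f in str(raw_flags).split(";") if f]
            if raw_flags is not None and not (isinstance(raw_flags, float) and math.isnan(raw_flags))
            else []
        )
        try:
            records.append(
                KneeRecord(
                    knee_id=str(row["knee_id"]),
                    group=str(row.get("group", "unknown")),
                    shape=str(row["shape"]).strip().lower(),
                    sulcus_angle=_opt_int(row["sulcus_angle"], i, "sulcus_angle"),
                    lti=_opt_int(row["lti"], i, "lti"),
                    cto=_opt_int(row["cto"], i, "cto"),
                    bump=_opt_int(row["bump_sagittal"], i, "bump_sagittal"),
                    bump_axial=_opt_int(row["bump_axial"], i, "bump_axial"),
                    dysplasia_type=_opt_int(row.get("dysplasia_type"), i, "dysplasia_type"),
                    flags=flags,
                )
            )
        except InvalidLandmarksError as exc:
            raise ValueError(f"row {i} (knee {row.get('knee_id')!r}): {exc}") from exc
    return records


def frame_from_records(records: Iterable[KneeRecord]) -> pd.DataFrame:
    """Serialize records to the measurements table (``NA`` for unmeasurable)."""
    rows = []
    for r in records:
        rows.append(
            {
                "knee_id": r.knee_id,
                "group": r.group,
                "shape": r.shape,
                "sulcus_angle": _NA if r.sulcus_angle is None else r.sulcus_angle,
                "lti": _NA if r.lti is None else r.lti,
                "cto": r.cto,
                "bump_axial": _NA if r.bump_axial is None else r.bump_axial,
                "bump_sagittal": r.bump,
                "dysplasia_type": _NA if r.dysplasia_type is None else r.dysplasia_type,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)


def read_measurements(path) -> list[KneeRecord]:
    """Read a measurements CSV (tolerates any line-ending dialect)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return records_from_frame(frame)


def write_measurements(records: Iterable[KneeRecord], path) -> None:
    frame_from_records(records).to_csv(path, index=False)


def read_landmarks(path) -> dict[str, tuple[AxialLandmarks, SagittalLandmarks]]:
    """Read a long-format landmarks CSV into per-knee landmark sets.

    Expected columns: knee_id, plane, point, x_mm, y_mm, shape. The MTC row
    may be absent only for convex knees.
    """
    frame = pd.read_csv(path)
    required = {"knee_id", "plane", "point", "x_mm", "y_mm", "shape"}
    if not required <= set(frame.columns):
        raise ValueError(f"landmarks table is missing columns: {sorted(required - set(frame.columns))}")
    out: dict[str, tuple[AxialLandmarks, SagittalLandmarks]] = {}
    for knee_id, sub in frame.groupby("knee_id", sort=False):
        points: dict[str, PlanePoint] = {}
        for _, row in sub.iterrows():
            name = str(row["point"]).strip().upper()
            if name not in _POINT_PLANES:
                raise ValueError(f"knee {knee_id!r}: unknown landmark {name!r}")
            points[name] = PlanePoint(float(row["x_mm"]), float(row["y_mm"]))
        shapes = {str(s).strip().lower() for s in sub["shape"]}
        if len(shapes) != 1:
            raise ValueError(f"knee {knee_id!r}: inconsistent shape labels {sorted(shapes)}")
        shape = shapes.pop()
        required_pts = set(_POINT_PLANES) - ({"MTC"} if shape == "convex" else set())
        missing_pts = required_pts - set(points)
        if missing_pts:
            raise ValueError(f"knee {knee_id!r}: missing landmarks {sorted(missing_pts)}")
        axial = AxialLandmarks(
            tgc=points["TGC"],
            ltc=points["LTC"],
            mtc=points.get("MTC"),
            l_point=points["L"],
            m_point=points["M"],
            posterior_medial=points["POST_MED"],
            posterior_lateral=points["POST_LAT"],
            anterior_cortex_tangent=points["ACT"],
            shape=shape,
        )
        sagittal = SagittalLandmarks(
            afcl_p1=points["AFCL1"],
            afcl_p2=points["AFCL2"],
            trochlear_apex=points["APEX"],
        )
        out[str(knee_id)] = (axial, sagittal)
    return out
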