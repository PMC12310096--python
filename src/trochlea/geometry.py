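"""Trochlear measurements from digitized 2D landmark coordinates.

All measurements operate on multiplanar-reconstruction-standardized planes:

* axial frame: +x runs medial→lateral, +y runs posterior→anterior;
* sagittal frame: +x runs caudal→cranial, +y runs posterior→anterior.

Angles and distances are rounded to the nearest whole unit (degrees / mm),
half away from zero, only at the final step of each measurement — never on
intermediates. Signed quantities (lateral trochlear inclination, cranial
trochlear orientation, both central bumps) are positive on the anterior
side of their reference line.

Convex trochleae have no sulcus and no medial facet, so the sulcus angle
and the lateral trochlear inclination are *unmeasurable* for them; both are
represented as ``None``, never as a numeric sentinel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "DegenerateGeometryError",
    "InvalidLandmarksError",
    "PlanePoint",
    "Line2D",
    "AxialLandmarks",
    "SagittalLandmarks",
    "KneeRecord",
    "SHAPES",
    "round_half_away",
    "compute_pbcl",
    "measure_sulcus_angle",
    "measure_lti",
    "measure_cto",
    "measure_bump_axial",
    "measure_bump_sagittal",
    "measure_knee",
]

SHAPES = ("concave", "flat", "convex")


class DegenerateGeometryError(ValueError):
    """Raised when a construction is geometrically undefined (e.g. a line
    through coincident points)."""


class InvalidLandmarksError(ValueError):
    """Raised when a landmark set violates a measurability invariant."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Matches clinical reporting of measurements "rounded to the nearest
    whole number"; Python's built-in banker's rounding would map 0.5 → 0.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class PlanePoint:
    """A digitized point in one MRI plane, in millimetres."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidLandmarksError(f"non-finite coordinates ({self.x}, {self.y})")

    def __sub__(self, other: "PlanePoint") -> tuple[float, float]:
        return (self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class Line2D:
    """An oriented line: an anchor point plus a unit direction vector."""

    anchor: PlanePoint
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        dx, dy = self.direction
        norm = math.hypot(dx, dy)
        if not math.isfinite(norm) or abs(norm - 1.0) > 1e-9:
            raise DegenerateGeometryError("line direction must be a unit vector")

    def signed_offset(self, p: PlanePoint) -> float:
        """Perpendicular offset of ``p`` from the line; positive on the
        left of the direction vector (= anterior for a medial→lateral or
        caudal→cranial oriented reference line)."""
        vx, vy = p - self.anchor
        dx, dy = self.direction
        return dx * vy - dy * vx

    def through(self, p: PlanePoint) -> "Line2D":
        """The parallel line translated to pass through ``p``."""
        return Line2D(p, self.direction)


@dataclass(frozen=True)
class AxialLandmarks:
    """Axial-plane landmarks for one knee.

    ``mtc`` (medial trochlear cartilage peak) is absent exactly when the
    trochlea is convex — a convex trochlea has no medial facet.
    ``anterior_cortex_tangent`` is the point where the translated posterior
    bicondylar line becomes tangent to the anterior femoral cortex on the
    most cranial slice.
    """

    tgc: PlanePoint
    ltc: PlanePoint
    l_point: PlanePoint
    m_point: PlanePoint
    posterior_medial: PlanePoint
    posterior_lateral: PlanePoint
    anterior_cortex_tangent: PlanePoint
    shape: str
    mtc: Optional[PlanePoint] = None

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise InvalidLandmarksError(f"unknown trochlear shape {self.shape!r}")
        if self.shape == "convex" and self.mtc is not None:
            raise InvalidLandmarksError("convex trochlea cannot have an MTC peak")
        if self.shape != "convex" and self.mtc is None:
            raise InvalidLandmarksError(f"{self.shape} trochlea requires an MTC peak")
        if (self.ltc.x, self.ltc.y) == (self.tgc.x, self.tgc.y):
            raise InvalidLandmarksError("LTC and TGC must be distinct points")


@dataclass(frozen=True)
class SagittalLandmarks:
    """Sagittal-plane landmarks: two points on the anterior femoral cortex
    line (AFCL) and the most anterior cartilage point through the groove."""

    afcl_p1: PlanePoint
    afcl_p2: PlanePoint
    trochlear_apex: PlanePoint

    def __post_init__(self) -> None:
        if (self.afcl_p1.x, self.afcl_p1.y) == (self.afcl_p2.x, self.afcl_p2.y):
            raise DegenerateGeometryError("AFCL requires two distinct points")


@dataclass
class KneeRecord:
    """One knee's rounded measurements with measurability flags.

    ``sulcus_angle`` and ``lti`` are ``None`` iff ``shape == "convex"``.
    ``bump`` holds the sagittal-plane central bump (the value used for
    classification); ``bump_axial`` is kept alongside it.
    """

    knee_id: str = ""
    group: str = "unknown"  # {OPI, control, unknown}
    shape: str = "flat"
    sulcus_angle: Optional[int] = None
    lti: Optional[int] = None
    cto: int = 0
    bump: int = 0
    bump_axial: Optional[int] = None
    dysplasia_type: Optional[int] = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise InvalidLandmarksError(f"unknown trochlear shape {self.shape!r}")
        convex = self.shape == "convex"
        if convex and (self.sulcus_angle is not None or self.lti is not None):
            raise InvalidLandmarksError(
                "sulcus angle and LTI must be unmeasurable (None) for convex trochleae"
            )
        if not convex and (self.sulcus_angle is None or self.lti is None):
            raise InvalidLandmarksError(
                "sulcus angle and LTI must be numeric for non-convex trochleae"
            )


def _unit(vx: float, vy: float, what: str) -> tuple[float, float]:
    n = math.hypot(vx, vy)
    if n < 1e-12:
        raise DegenerateGeometryError(f"{what}: coincident points")
    return (vx / n, vy / n)


def compute_pbcl(posterior_medial: PlanePoint, posterior_lateral: PlanePoint) -> Line2D:
    """Posterior bicondylar line through the posterior subchondral bone of
    both condyles, oriented medial→lateral (positive x-component)."""
    dx, dy = _unit(*(posterior_lateral - posterior_medial), what="PBCL")
    if dx < 0 or (dx == 0 and dy < 0):
        dx, dy = -dx, -dy
    return Line2D(posterior_medial, (dx, dy))


def _line_angle_signed(ref: Line2D, base: PlanePoint, tip: PlanePoint, what: str) -> float:
    """Unsigned angle between line base–tip and ``ref``, signed by the side
    of ``tip`` relative to ``ref`` translated through ``base`` (+ anterior)."""
    vx, vy = tip - base
    if math.hypot(vx, vy) < 1e-12:
        raise DegenerateGeometryError(f"{what}: coincident points")
    dx, dy = ref.direction
    cross = dx * vy - dy * vx
    dot = dx * vx + dy * vy
    angle = math.degrees(math.atan2(abs(cross), abs(dot)))
    return math.copysign(angle, cross) if cross != 0 else 0.0


def measure_sulcus_angle(lm: AxialLandmarks) -> Optional[int]:
    """Sulcus angle at TGC between rays TGC→LTC and TGC→MTC, degrees.

    Returns ``None`` (unmeasurable) for convex trochleae.
    """
    if lm.shape == "convex":
        return None
    ux, uy = _unit(*(lm.ltc - lm.tgc), what="sulcus angle LTC ray")
    vx, vy = _unit(*(lm.mtc - lm.tgc), what="sulcus angle MTC ray")
    dot = max(-1.0, min(1.0, ux * vx + uy * vy))
    return round_half_away(math.degrees(math.acos(dot)))


def measure_lti(lm: AxialLandmarks, pbcl: Line2D) -> Optional[int]:
    """Lateral trochlear inclination: angle between the lateral-facet line
    (LTC–TGC) and the PBCL, positive when LTC is anterior to the PBCL
    translated through TGC. ``None`` for convex trochleae."""
    if lm.shape == "convex":
        return None
    return round_half_away(_line_angle_signed(pbcl, lm.tgc, lm.ltc, "LTI"))


def measure_cto(lm: AxialLandmarks, pbcl: Line2D) -> int:
    """Cranial trochlear orientation: angle between the L–M line and the
    PBCL, positive when M is anterior to the PBCL translated through L.
    Defined for all shapes."""
    return round_half_away(_line_angle_signed(pbcl, lm.l_point, lm.m_point, "CTO"))


def measure_bump_axial(
    tgc: PlanePoint, anterior_cortex_tangent: PlanePoint, pbcl: Line2D
) -> int:
    """Axial central bump: signed perpendicular distance (mm) from the PBCL
    translated through the anterior-cortex tangent point to TGC, positive
    when TGC is anterior."""
    return round_half_away(pbcl.through(anterior_cortex_tangent).signed_offset(tgc))


def measure_bump_sagittal(lm: SagittalLandmarks) -> int:
    """Sagittal central bump: signed perpendicular distance (mm) from the
    anterior femoral cortex line to the trochlear apex, positive anterior."""
    dx, dy = _unit(*(lm.afcl_p2 - lm.afcl_p1), what="AFCL")
    if dx < 0 or (dx == 0 and dy < 0):  # orient caudal→cranial
        dx, dy = -dx, -dy
    afcl = Line2D(lm.afcl_p1, (dx, dy))
    return round_half_away(afcl.signed_offset(lm.trochlear_apex))


def measure_knee(
    axial: AxialLandmarks,
    sagittal: SagittalLandmarks,
    knee_id: str = "",
    group: str = "unknown",
) -> KneeRecord:
    """Run all measurements on one knee's landmark sets."""
    pbcl = compute_pbcl(axial.posterior_medial, axial.posterior_lateral)
    return KneeRecord(
        knee_id=knee_id,
        group=group,
        shape=axial.shape,
        sulcus_angle=measure_sulcus_angle(axial),
        lti=measure_lti(axial, pbcl),
        cto=measure_cto(axial, pbcl),
        bump=measure_bump_sagittal(sagittal),
        bump_axial=measure_bump_axial(axial.tgc, axial.anterior_cortex_tangent, pbcl),
    )
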