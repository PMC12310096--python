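import math

import numpy as np
import pytest

from trochlea.geometry import AxialLandmarks, KneeRecord, PlanePoint, SagittalLandmarks


def make_record(sulcus=150, lti=16, bump=3, shape=None, group="unknown", **kw):
    """KneeRecord shorthand: pass sulcus=None, lti=None for a convex knee."""
    if shape is None:
        shape = "convex" if sulcus is None else "concave"
    return KneeRecord(
        shape=shape, sulcus_angle=sulcus, lti=lti, bump=bump, group=group, **kw
    )


@pytest.fixture
def concave_axial():
    return AxialLandmarks(
        tgc=PlanePoint(0, 0),
        ltc=PlanePoint(-20, 8),
        mtc=PlanePoint(15, 6),
        l_point=PlanePoint(25, 0),
        m_point=PlanePoint(-20, -5),
        posterior_medial=PlanePoint(-25, -35),
        posterior_lateral=PlanePoint(25, -35),
        anterior_cortex_tangent=PlanePoint(-5, -6),
        shape="concave",
    )


@pytest.fixture
def sagittal_set():
    return SagittalLandmarks(
        afcl_p1=PlanePoint(0, 0),
        afcl_p2=PlanePoint(10, 0),
        trochlear_apex=PlanePoint(-30, 4.6),
    )


def rigid_transform(theta_deg, tx, ty):
    """A rigid 2D transform (rotation then translation) acting on PlanePoints."""
    c, s = math.cos(math.radians(theta_deg)), math.sin(math.radians(theta_deg))

    def apply(p: PlanePoint) -> PlanePoint:
        return PlanePoint(c * p.x - s * p.y + tx, s * p.x + c * p.y + ty)

    return apply


def transform_axial(lm: AxialLandmarks, f) -> AxialLandmarks:
    return AxialLandmarks(
        tgc=f(lm.tgc),
        ltc=f(lm.ltc),
        mtc=None if lm.mtc is None else f(lm.mtc),
        l_point=f(lm.l_point),
        m_point=f(lm.m_point),
        posterior_medial=f(lm.posterior_medial),
        posterior_lateral=f(lm.posterior_lateral),
        anterior_cortex_tangent=f(lm.anterior_cortex_tangent),
        shape=lm.shape,
    )


def transform_sagittal(lm: SagittalLandmarks, f) -> SagittalLandmarks:
    return SagittalLandmarks(
        afcl_p1=f(lm.afcl_p1), afcl_p2=f(lm.afcl_p2), trochlear_apex=f(lm.trochlear_apex)
    )
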