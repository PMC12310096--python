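"""Synthetic cohorts and landmark fixtures.

Two generators make the whole pipeline testable without MRI data:

* :func:`generate_cohort` draws measurement-level knees with the group-wise
  statistical structure of the study cohort (127 knees with objective
  patellar instability, 103 meniscal-tear controls): trochlear shape from
  the group shape frequencies, then sulcus angle, LTI, CTO and both bumps
  from truncated normals matching the published group means, SDs and
  observed ranges. Convex knees get genuinely absent (``None``) sulcus and
  LTI values. Sulcus angle and LTI are coupled through a Gaussian copula
  whose default rank correlation (:data:`SULCUS_LTI_RHO`) is calibrated to
  the published joint screening-criterion counts; CTO and the bumps are
  drawn independently (no covariances are published for them).

* :func:`generate_landmarks` runs the measurement constructions backwards:
  given target measurements it places landmarks (PBCL along +x, TGC at the
  origin, lateral facet at 20 mm radius) such that measuring them
  reproduces the targets exactly after rounding.

The generator emulates marginal distributions and measurability, not
reader placement error or anatomical covariation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    AxialLandmarks,
    KneeRecord,
    PlanePoint,
    SagittalLandmarks,
    round_half_away,
)
from .classification import ClassificationConfig, classify_option
from .diagnostics import confusion, sens_spec
from .thresholding import derive_thresholds

__all__ = [
    "TruncatedNormalSpec",
    "GroupParams",
    "CohortSpec",
    "OPI_PARAMS",
    "CONTROL_PARAMS",
    "DEFAULT_PARAMS",
    "generate_cohort",
    "generate_landmarks",
    "recovery_experiment",
]


@dataclass(frozen=True)
class TruncatedNormalSpec:
    """Mean, SD and truncation range of one measurement in one group."""

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not self.low <= self.mean <= self.high:
            raise ValueError("truncation range must contain the mean")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return stats.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class GroupParams:
    """Distributional parameters of one cohort group."""

    shape_probs: tuple[float, float, float]  # concave, flat, convex
    sulcus: TruncatedNormalSpec
    lti: TruncatedNormalSpec
    cto: TruncatedNormalSpec
    bump: TruncatedNormalSpec  # sagittal plane
    bump_axial: TruncatedNormalSpec

    def __post_init__(self) -> None:
        if abs(sum(self.shape_probs) - 1.0) > 1e-9 or min(self.shape_probs) < 0:
            raise ValueError("shape probabilities must be nonnegative and sum to 1")


# Group parameters of the study cohort: shape counts 16/68/43 of 127 (OPI)
# and 81/20/2 of 103 (control); measurement means +/- SD with observed ranges.
OPI_PARAMS = GroupParams(
    shape_probs=(16 / 127, 68 / 127, 43 / 127),
    sulcus=TruncatedNormalSpec(160.0, 7.6, 140, 180),
    lti=TruncatedNormalSpec(11.3, 4.3, 0, 20),
    cto=TruncatedNormalSpec(-2.3, 8.3, -38, 22),
    bump=TruncatedNormalSpec(6.0, 2.2, 1, 12),
    bump_axial=TruncatedNormalSpec(6.0, 2.1, 1, 12),
)

CONTROL_PARAMS = GroupParams(
    shape_probs=(81 / 103, 20 / 103, 2 / 103),
    sulcus=TruncatedNormalSpec(149.2, 6.1, 134, 167),
    lti=TruncatedNormalSpec(16.7, 3.7, 9, 29),
    cto=TruncatedNormalSpec(-10.8, 5.1, -26, -1),
    bump=TruncatedNormalSpec(2.8, 1.8, -2, 8),
    bump_axial=TruncatedNormalSpec(2.8, 1.9, -2, 8),
)

DEFAULT_PARAMS = {"OPI": OPI_PARAMS, "control": CONTROL_PARAMS}


#: Default Spearman correlation between sulcus angle and LTI within a group.
#: A shallower trochlea both widens the sulcus angle and flattens the lateral
#: facet, so the two are strongly negatively dependent; the value is
#: calibrated once so that the simulated joint proportions of
#: "sulcus >= 157 AND LTI < 14" and "... OR ..." among measurable knees
#: match the study's published screening-criterion counts in both groups.
#: Under independence the OR-criterion sensitivity simulates ~7 points too
#: high. CTO and the bumps stay independent of everything else.
SULCUS_LTI_RHO = -0.75


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, seed and the sulcus-LTI rank correlation."""

    n_opi: int = 127
    n_control: int = 103
    seed: int = 0
    correlation: float = SULCUS_LTI_RHO  # Spearman rho, sulcus angle vs LTI

    def __post_init__(self) -> None:
        if self.n_opi < 1 or self.n_control < 1:
            raise ValueError("need at least one knee per group")
        if not -1 < self.correlation < 1:
            raise ValueError("rank correlation must lie in (-1, 1)")


def _draw_group(
    rng: np.random.Generator,
    n: int,
    group: str,
    params: GroupParams,
    correlation: float,
    start_index: int,
) -> list[KneeRecord]:
    shapes = rng.choice(["concave", "flat", "convex"], size=n, p=params.shape_probs)
    # Gaussian copula: correlated uniforms for sulcus and LTI
    rho = 2.0 * math.sin(math.pi * correlation / 6.0)  # Spearman -> Pearson
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    u_sulcus, u_lti = stats.norm.cdf(z[:, 0]), stats.norm.cdf(z[:, 1])
    sulcus = params.sulcus.ppf(u_sulcus)
    lti = params.lti.ppf(u_lti)
    cto = params.cto.ppf(rng.uniform(size=n))
    bump = params.bump.ppf(rng.uniform(size=n))
    bump_ax = params.bump_axial.ppf(rng.uniform(size=n))
    records = []
    for i in range(n):
        convex = shapes[i] == "convex"
        records.append(
            KneeRecord(
                knee_id=f"{group}-{start_index + i:04d}",
                group=group,
                shape=str(shapes[i]),
                sulcus_angle=None if convex else round_half_away(sulcus[i]),
                lti=None if convex else round_half_away(lti[i]),
                cto=round_half_away(cto[i]),
                bump=round_half_away(bump[i]),
                bump_axial=round_half_away(bump_ax[i]),
            )
        )
    return records


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
    params: Optional[dict[str, GroupParams]] = None,
) -> list[KneeRecord]:
    """Draw a labeled two-group cohort of knee measurement records."""
    params = DEFAULT_PARAMS if params is None else params
    rng = np.random.default_rng(spec.seed)
    return _draw_group(rng, spec.n_opi, "OPI", params["OPI"], spec.correlation, 0) + _draw_group(
        rng, spec.n_control, "control", params["control"], spec.correlation, 0
    )


def generate_landmarks(
    sulcus: Optional[float] = None,
    lti: Optional[float] = None,
    cto: float = 0.0,
    bump: float = 0.0,
    shape: str = "flat",
    bump_axial: Optional[float] = None,
) -> tuple[AxialLandmarks, SagittalLandmarks]:
    """Place landmarks realizing the requested measurements exactly.

    Geometry: PBCL along +x through posterior condyle points at y = -35;
    TGC at the origin; LTC on a 20 mm radius at elevation ``lti``; MTC on a
    15 mm radius so the angle at TGC equals ``sulcus``; L-M line of 45 mm
    realizing ``cto``; the anterior-cortex tangent point and AFCL placed so
    the perpendicular offsets equal the bumps. For convex shapes sulcus and
    LTI must be omitted (they are unmeasurable) and the lateral facet is
    placed flat.
    """
    convex = shape == "convex"
    if convex and (sulcus is not None or lti is not None):
        raise ValueError("sulcus angle and LTI cannot be targeted for a convex trochlea")
    if not convex:
        if sulcus is None or lti is None:
            raise ValueError(f"{shape} trochlea requires sulcus and LTI targets")
        if not 0 < sulcus <= 180:
            raise ValueError(f"sulcus angle must lie in (0, 180], got {sulcus}")
        if not -90 < lti < 90:
            raise ValueError(f"LTI must lie in (-90, 90), got {lti}")
    if not -90 < cto < 90:
        raise ValueError(f"CTO must lie in (-90, 90), got {cto}")
    bump_axial = bump if bump_axial is None else bump_axial

    tgc = PlanePoint(0.0, 0.0)
    lam = math.radians(0.0 if convex else lti)
    ltc = PlanePoint(-20.0 * math.cos(lam), 20.0 * math.sin(lam))
    if convex:
        mtc = None
    else:
        theta_m = math.radians(180.0 - lti - sulcus)
        mtc = PlanePoint(15.0 * math.cos(theta_m), 15.0 * math.sin(theta_m))
    gam = math.radians(cto)
    l_point = PlanePoint(24.0, 0.0)
    m_point = PlanePoint(24.0 - 45.0 * math.cos(gam), 45.0 * math.sin(gam))
    axial = AxialLandmarks(
        tgc=tgc,
        ltc=ltc,
        mtc=mtc,
        l_point=l_point,
        m_point=m_point,
        posterior_medial=PlanePoint(-25.0, -35.0),
        posterior_lateral=PlanePoint(25.0, -35.0),
        anterior_cortex_tangent=PlanePoint(-5.0, -float(bump_axial)),
        shape=shape,
    )
    sagittal = SagittalLandmarks(
        afcl_p1=PlanePoint(-10.0, 0.0),
        afcl_p2=PlanePoint(30.0, 0.0),
        trochlear_apex=PlanePoint(5.0, float(bump)),
    )
    return axial, sagittal


def recovery_experiment(
    spec: CohortSpec = CohortSpec(),
    params: Optional[dict[str, GroupParams]] = None,
    n_reps: int = 100,
) -> dict:
    """Repeatedly simulate the study and re-derive thresholds.

    Per replicate: draw a cohort, fit the three single-split cutpoints, and
    evaluate the 'sulcus >= cut OR LTI < cut' screening criterion (Option 4,
    at the derived cutpoints) against group labels. Returns per-replicate
    results and a median/IQR summary.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_reps) % (2**31)
    rows = []
    for rep, s in enumerate(seeds):
        rep_spec = CohortSpec(spec.n_opi, spec.n_control, int(s), spec.correlation)
        cohort = generate_cohort(rep_spec, params)
        rules = derive_thresholds(cohort)
        cfg = ClassificationConfig(
            sulcus_cut=max(1, int(rules["sulcus_angle"].cutpoint)),
            lti_cut=max(1, int(rules["lti"].cutpoint)),
        )
        cm = confusion(
            [classify_option(r, 4, cfg) for r in cohort],
            [r.group == "OPI" for r in cohort],
        )
        sens, spc = sens_spec(cm)
        rows.append(
            {
                "replicate": rep,
                "sulcus_cut": rules["sulcus_angle"].cutpoint,
                "lti_cut": rules["lti"].cutpoint,
                "bump_cut": rules["bump"].cutpoint,
                "option4_sensitivity_pct": sens,
                "option4_specificity_pct": spc,
            }
        )
    replicates = pd.DataFrame(rows).set_index("replicate")
    summary = replicates.describe(percentiles=[0.25, 0.5, 0.75]).loc[
        ["25%", "50%", "75%"]
    ]
    return {"replicates": replicates, "summary": summary}
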