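# Methods

## Coordinate frames and measurement conventions

All geometry operates on landmarks digitized in multiplanar-reconstruction
(MPR) standardized planes, in millimetres:

* axial plane: +x medial→lateral, +y posterior→anterior;
* sagittal plane: +x caudal→cranial, +y posterior→anterior.

Reference lines are oriented by forcing a positive x-component on their
unit direction (medial→lateral for the posterior bicondylar line, PBCL;
caudal→cranial for the anterior femoral cortex line, AFCL). "Anterior" is
then the positive side of the cross product of the line direction with the
point offset, which makes every signed measurement deterministic:

* **sulcus angle** — angle at the trochlear groove cartilage point (TGC)
  between the rays to the lateral (LTC) and medial (MTC) cartilage peaks;
  unsigned, in (0°, 180°].
* **LTI** — angle between the lateral-facet line LTC–TGC and the PBCL,
  positive when LTC is anterior to the PBCL translated through TGC.
* **CTO** — angle between the L–M line (most lateral / most medial
  cartilage-covered points on the most cranial trochlear slice) and the
  PBCL, positive when M is anterior.
* **central bump** — signed perpendicular distance from the PBCL translated
  to the anterior-cortex tangent point (axial) or from the AFCL (sagittal)
  to the trochlear groove point, positive anterior. Negative bumps occur in
  deep trochleae.

Measurements are rounded to the nearest whole degree / millimetre, half
away from zero, only at the end of each construction; intermediates keep
full precision. Convex trochleae (no sulcus, no medial facet) have
unmeasurable sulcus angle and LTI, represented as `None` end to end and as
the token `NA` in CSV — never a numeric sentinel.

Because of the positive-x orientation rule, signed measurements are
invariant under rigid transforms that keep the frame orientation (rotations
strictly inside ±90°) and flip sign exactly under reflection across the
PBCL. Rotations beyond ±90° would swap the anatomical axis orientation and
cannot occur on MPR-standardized images; the invariance tests therefore
sample rotations within ±85°. Slice selection (scrolling cranial→caudal to
the first qualifying slice) is an imaging step: the module takes the
selected slice's landmarks as input and treats coordinates as exact, since
no reader placement tolerance is published.

## Classification

The four-type rule is evaluated with cutpoints `sulcus_cut` (default 157°),
`lti_cut` (14°) and `bump_cut` (5 mm), on the sagittal bump by default
(configurable to axial). The four published clauses are mutually exclusive
and exhaustive, which the tests verify by exhaustive enumeration over the
integer measurement grid against a verbatim-clause oracle. Two deliberate
consequences of the clause order:

* Type 0 ignores the bump. A knee with normal sulcus angle and LTI but a
  bump ≥ 5 mm is Type 0 and is flagged (`type0_with_bump`) rather than
  reclassified — such knees exist in the reference data.
* In the Option screening criteria, an unmeasurable value satisfies its
  clause (a convex trochlea is maximally dysplastic on both quantities);
  this is the only reading consistent with the published screening counts.

## Threshold derivation

Cutpoints are re-derived per parameter by a depth-one CART split: an
exhaustive search over rules `value ≥ c`, `c` ranging over observed unique
values with both children nonempty, minimizing the weighted Gini impurity
(entropy optional); ties go to the smallest cutpoint, and the rule
direction follows whichever side is case-enriched. There is no tree growth,
pruning or complexity parameter — the method reports exactly one cutpoint
per parameter. Splits whose impurity decrease is ≤ 1e-9 are flagged
uninformative. Unmeasurable values are excluded from fitting (a threshold
on a nonexistent value is undefined) and the exclusion count is reported on
the rule; convex knees re-enter at classification time through the
unmeasurability clauses.

## Diagnostic statistics

* Sensitivity/specificity are reported as integer percent (screening-table
  style); per-type prevalence as one-decimal percent.
* Odds ratios use the cross-product estimate with the Woolf log-scale 95%
  CI, `exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d))`; zero cells yield a flagged
  0/∞ estimate or, with the continuity option, Haldane–Anscombe 0.5
  correction. The CI method for the reference study's ORs is unstated, so
  CIs are not treated as reference values.
* Mean differences use the pooled-variance two-sample t interval; from
  summary means only the point estimate is produced.
* Sample size inverts the exact noncentral-t power function: for n per
  group the one-sided two-sample t statistic has df = 2n−2 and
  noncentrality d·√(n/2); the smallest n with power ≥ target is returned.
  The exact distribution matters: a normal approximation gives 17 and 31
  per group for the two designs of interest (d = 1.24 and 0.923 at
  α = 0.025, power 0.95) where the exact answer is 18 and 32.

## Agreement

Continuous measurements use ICC(2,1) — two-way random effects, absolute
agreement, single measures — computed from the two-way ANOVA mean squares
`(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`, with the standard
F-based (Satterthwaite df) confidence interval. Absolute agreement is the
right variant here because a systematic reader offset is a real
disagreement for threshold-based classification; consistency and
average-measure variants are available via `model`. Missing ratings are
handled by complete-case deletion. The implementation is validated against
an independent sums-of-squares oracle and against `pingouin`'s ICC2 row.

Categorical shape uses unweighted Gwet's AC1,
`(p_a − p_e)/(1 − p_e)` with `p_a` the mean pairwise agreement per subject
and `p_e = Σ_q π_q(1−π_q)/(Q−1)`. AC1's chance term stays calibrated under
prevalence imbalance (most control trochleae are concave), where kappa
collapses. The CI is a subject-level jackknife normal interval, truncated
to [−1, 1]; the CI method for the reference coefficients is unstated, so
the jackknife is a documented choice. Degenerate grids (constant ratings,
single-category label set) report 1 with a warning.

## Synthetic cohort generator

`generate_cohort` emulates the reference study's conditions: group sizes
127 (objective patellar instability, OPI) and 103 (controls); trochlear
shape drawn from the group frequencies (16/68/43 and 81/20/2 for
concave/flat/convex); sulcus angle, LTI, CTO and both bumps from truncated
normals at the published group means, SDs and observed ranges (e.g. OPI
sulcus 160.0 ± 7.6° on [140°, 180°], control 149.2 ± 6.1° on
[134°, 167°]); all values rounded to integers; convex knees get absent
sulcus/LTI.

Sulcus angle and LTI are coupled through a Gaussian copula. A shallower
trochlea simultaneously widens the sulcus angle and flattens the lateral
facet, and the published joint screening counts (among measurable OPI
knees, 53/84 satisfy *both* "sulcus ≥ 157°" and "LTI < 14°" against an
independence expectation of ≈ 0.52·84 ≈ 43) confirm strong negative
dependence. The default Spearman ρ = −0.75 was calibrated once by matching
the simulated AND/OR joint proportions to those published counts in both
groups and then frozen; under independence the OR-criterion sensitivity
simulates roughly seven points above the reference value. CTO and the
bumps are drawn independently — no covariances involving them are
published — which mildly understates any real joint structure between bump
and the other measurements.

What the generator does **not** emulate: reader placement error,
anatomical covariation beyond the single calibrated pair, sex- or
centre-specific structure, and any correlation between the axial and
sagittal bump (drawn independently despite near-identical marginals).
Passing recovery tests therefore show that the estimation pipeline recovers
the published cutpoints *under these idealized conditions*, not that it
would on new clinical data.

`generate_landmarks` inverts the geometry: PBCL along +x, TGC at the
origin, LTC at 20 mm radius with elevation = LTI, MTC at 15 mm placed so
the vertex angle equals the sulcus angle, a 45 mm L–M segment realizing the
CTO, and tangent/AFCL offsets realizing the bumps. Measuring the output
reproduces integer targets exactly, which the suite checks for 1,000 random
target tuples.

`recovery_experiment` repeats generate→derive-thresholds→screen; with the
default conditions and 100 replicates (seconds of runtime) the median
derived cutpoints land near 157° / 14° / 5 mm and median OR-criterion
sensitivity near 87%. The published real-data values (exact thresholds
157/14/5, type counts 93/42/9/86, ICC 0.863) are anchors, not exactly
reproducible quantities: they depend on the original cohort, which is not
deposited.

## Numerical and interface choices

* Rounding: half away from zero (clinical convention), applied once per
  measurement.
* Degenerate geometry (coincident points, zero-length directions) raises
  `DegenerateGeometryError`; measurability violations raise
  `InvalidLandmarksError`; both are `ValueError` subclasses.
* Measurement CSVs store integers with `NA` for unmeasurable; the landmark
  path keeps full precision until final rounding. All CLI commands are
  deterministic given inputs and seed.
* Cutpoints are reported on the integer measurement scale in the printed
  inequality form (`≥ 157`, `< 14`, `≥ 5`).
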