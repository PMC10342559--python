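# Methods

## Coordinate frames and calibration

Landmark files are in image coordinates: pixels, x to the viewer's right,
y downward. Landmark names follow the subject's anatomical side (`EN_R` is
the subject's right endocanthion and appears on the image's left half);
the two chain vocabularies (`HL_p1..HL_p9` across the hairline, `P1..P13`
along the lower contour) are numbered in the viewer's left-to-right
direction, so `P1` — conventionally the "left" earlobe in viewer terms —
is the subject's right one. Nothing numerical depends on this: the
construction and all reported quantities are bilateral averages.

Metric conversion multiplies pixel coordinates by
`scale = reference_corneal_mm / corneal_diameter_px` and flips the y-axis so
metric y points superiorly. The reference white-to-white corneal diameter
is 11.71 mm (`--corneal-mm` to override); its ±0.42 mm population spread is
**not** propagated into point estimates — a per-face bias of up to ~3.6%
in absolute lengths is possible if a subject's cornea deviates that far,
and this is a stated caveat of iris-diameter photogrammetry rather than
something the pipeline can estimate from a single photo. When both eyes
carry limbus points the per-eye diameters are averaged (symmetric, lower
variance); one eye suffices.

## Pose and angle conventions

The face-rotation angle is the signed angle between the glabella→menton
vector and the image vertical, positive when the face is turned clockwise
as the viewer sees it. Linear measurements are never rotation-corrected (a
rigid rotation cannot change a distance). Canthal tilt is the elevation of
the endocanthion→exocanthion line above the image horizontal, measured
along the medial→lateral direction and signed positive when the lateral
canthus is superior (the clinical convention). The rotation correction
enters with opposite signs for the two eyes — subtracted for the subject's
right eye, added for the left — because a clockwise head tilt raises one
canthal line's apparent elevation and lowers the other's; this is the only
sign assignment under which the averaged corrected tilt is invariant to
rigid rotation (verified to 1e-6° in tests).

Brow angles are measured against the interpupillary line: angle 1 is the
medial brow line's elevation (signed positive when the brow peak is
superior — an upward-slanting medial brow), angle 2 the angle between the
medial and lateral brow lines, angle 3 the lateral brow line's unsigned
slope. Using the interpupillary reference already makes these head-tilt
invariant, so no additional rotation correction is applied. For straight
brow segments angle 2 equals angle 1 + angle 3; the reference tables
satisfy this identity to ~0.2°, which corroborates the geometric reading.

## The measurement battery

All internal computation is in millimetres at full precision; linear
outputs are centimetres, reports round to 2 decimals (matching the
reference tables) while machine-readable companions keep 4. Bilateral
quantities are computed per side and averaged; total brow length is the
medial + lateral arc sum, not the end-to-end chord. `measure_face` fills
fields at per-field granularity and leaves anything whose landmarks are
absent as missing (`None`), never zero — partial batteries stay usable,
and the per-block functions raise instead for strict use. Degenerate
geometry (coincident points where a direction is needed) raises
explicitly; a zero nose length is allowed but is a quality-control signal.

A reference-table inconsistency is resolved here once: the printed
glabella→subnasale ("mid facial height") means of 3.53/3.67 cm contradict
midline additivity (facial 19.00/20.40 − forehead 6.03/5.98 − lower
6.40/7.53 leaves 6.57/6.89 cm) and the same tables' height:midface ratio
(2.90/2.97 ≈ 19.00/6.57, 20.40/6.89) and horizontal thirds (1:1.09:1.06,
1:1.15:1.26 — mid components 6.57/6.03 and 6.89/5.98). The measurement is
implemented exactly as defined (glabella to subnasale); the synthetic
template places the glabella so the midline is additive, making the
consistent 6.57/6.89 cm values its targets, and the preset module keeps
the printed numbers verbatim for reference. Similarly, the printed female
"Avg M3/M11 = 5.81" row disagrees with its own components (5.73, 5.60);
averages are always recomputed from components, and a printed
"average palpebral fissure height 0.03" row is treated as a typographical
artifact (the average of 0.96 and 0.95 cannot be 0.03).

## Proportions and thirds

R1–R10 are plain ratios of named measurements. Cohort-level proportions
are computed per subject and then averaged (mean of ratios) — the only
convention compatible with the reference tables' per-ratio SDs — which is
why a ratio of printed means (e.g. 19.00/13.63 = 1.39) can differ in the
second decimal from a printed cohort ratio (1.40). Horizontal thirds are
normalised to the upper third; vertical thirds to the mean of the two
outer segments, the only normalisation that can print a symmetric `1:x:1`
on real, slightly asymmetric faces.

## Group statistics, validation, power

Welch's t-test is the default two-group test; the reference analysis never
names its test, and Welch is the robust choice for 21-per-group cohorts
with unequal SDs. Mann-Whitney is selectable, with the exact permutation
null whenever both groups have ≤ 12 tie-free observations and the
tie-corrected normal approximation otherwise; the same exact/approximate
switch governs the Wilcoxon signed-rank test used for paired validation
(all-zero difference vectors return a missing p-value). Both rank tests
are verified against exhaustive enumeration of the null (all group
assignments / all 2^n sign flips) for n ≤ 8. No multiple-testing
correction is applied, each measurement being judged at p < 0.05 on its
own, mirroring the reference analysis; with ~60 endpoints the family-wise
error is accordingly high, which reports should keep in mind.

The sample-size helper solves the standard noncentral-t power equation
(statsmodels) at Cohen's d with pooled SD and returns the smallest even
total. For the reference scenario — mandibular widths 9.35 ± 0.57 vs
8.70 ± 0.56 cm, power 0.95, α 0.05, d ≈ 1.15 — the standard computation
gives a total of 42; the reference narrative's "total sample of 18" is not
recoverable from any standard two-sample formula at these inputs and is
reported as a discrepancy, not matched.

## The synthetic cohort generator

The generator emulates the *statistical structure* of the reference
cohorts: per face it samples each target measurement independently from
its published (mean, SD) Gaussian truncated at ±3 SD (lengths floored at
0.05 cm), deforms a fixed anatomically ordered template so that the
measurement battery inverts the construction exactly, adds annotation
jitter, applies a random head rotation, and converts to pixels at a
sampled corneal diameter with consistent limbus points.

Template construction: midline points are placed collinearly (subnasale at
the origin, menton at −lower height, glabella at the additive mid height,
trichion above it); irises at ±IPD/2 with canthi on a line tilted by the
sampled canthal tilt; brows as two straight segments with the sampled
lengths and angles, anchored on the circle around the endocanthion that
matches the medial brow–canthus distance, choosing the superior
intersection that also matches the lateral brow–canthus distance; hairline
points vertically above their eyebrow counterparts at the sampled forehead
heights; contour points on anatomically pinned vertical lines (gonion x,
exocanthion x, cheilion x, endocanthion x, cupid's-bow x) at the sampled
subnasale distances, the distance always honoured exactly.

Two joint constraints can be infeasible under independent sampling and are
reconciled by a weighted least-squares compromise rather than rejection
(rejection would bias the recovered means): the gonion triple (m2, m12,
bigonial width) must satisfy the triangle inequality — violated in roughly
a third of draws, because these three are strongly positively correlated
in real faces while only marginals are published — and the brow-anchor
circle can miss the lateral-canthus sphere (rare). The gonion deficit is
split across the three values with weights proportional to their table
SDs; measured at n = 3000, this shifts the generated means of
m2/m12/bigonial width by about +0.07/+0.07/−0.11 cm, i.e. ~1% of the
quantity — the template's documented compromise tolerance. Every other
target is recovered exactly in noiseless mode (tests assert ≤ 1e-6
relative).

Noise defaults (the study conditions, chosen once): anatomical landmark
jitter 0.3 mm SD per coordinate — sub-millimetre manual-annotation error,
≈ 3 px at a typical 10 px/mm portrait scale — and 0.1 mm for the
high-contrast limbus points, whose error acts *multiplicatively* on every
measurement through the calibration scale (0.3 mm there would already
inflate all measured SDs by ~4%); head rotation N(0, 3°); corneal diameter
120 ± 12 px (arbitrary but realistic; a test asserts the pipeline is
exactly invariant to it). Jitter inflates measured SDs by
`sqrt(sd² + 2·jitter²)` for distances — about +10% for the smallest
measurement (palpebral fissure height) and < 2% for large ones — which the
recovery tests model explicitly.

What the generator does **not** emulate: inter-measurement correlations
(only marginals are published, so e.g. facial height and lower facial
height are sampled independently and the emergent brow angle 2 has SD
≈ 10.2° where the reference prints 8.12°, the deficit being the unmodelled
negative correlation of angles 1 and 3); non-Gaussian tails; asymmetric
faces beyond what independent left/right targets produce; out-of-plane
pose; and anything photographic. Passing tests therefore demonstrate that
the *pipeline* is correct and that cohorts with the published marginal
structure reproduce the published comparisons — not that the generator
captures real facial covariance.

## Contours

The 24 outline landmarks are the nine hairline points, the two zygomas and
the thirteen jawline points — the only named-point combination of that
size spanning the drawn facial outline. Alignment is subnasale translation
plus midline de-rotation only; size is deliberately preserved because
absolute size differences between groups are a finding. The group mean is
the pointwise mean of aligned coordinates; with mirror-paired inputs it is
bilaterally symmetric to 1e-6 mm, and a single face's mean is its own
alignment.

## Problem sizes and seeds

The study-reproduction scripts and acceptance checks use the reference
cohort size, 21 faces per group, at seed 42 (the package's documented
example seed); distributional property tests use 200 faces per group,
where standard errors are small enough to separate implementation error
from sampling noise while keeping the whole suite a few seconds; the
replicate stability check uses 20 seeded repetitions. Rank-test oracles
enumerate exactly up to n = 8 (6435 assignments / 256 sign patterns).

## Known limitations

* Frontal, in-plane 2D analysis; no yaw/pitch handling beyond the stated
  rotation model.
* Iris-diameter calibration inherits the corneal-diameter population
  spread as a per-face scale uncertainty.
* The validation harness quantifies annotation-jitter error only; detector
  bias (systematically misplaced landmarks) is outside its model.
* Mean contours average landmark positions, not curves; no spline
  interpolation or shape-space (Procrustes) analysis is attempted.
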