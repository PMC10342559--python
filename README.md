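# facemorph

Landmark-based frontal facial morphometry in Python: from named 2D facial
landmarks in pixel coordinates to calibrated metric measurements, facial
proportions, two-group sexual-dimorphism statistics, and mean facial
contours.

The package targets quantitative facial analysis as used in facial
rejuvenation and facial gender-affirming surgery (FGAS) planning: given
per-photo landmark annotations (from any detector or manual grading), it
computes a reproducible battery of soft-tissue measurements and the group
statistics surgeons consult when counselling patients. Because such studies
rarely release raw coordinates, the package ships a synthetic cohort
generator that emits landmark sets whose measurement distributions match
published gender-specific means and SDs of a 21-female / 21-male reference
cohort, so the entire pipeline runs and is tested end to end without any
photographs.

## The method

**Calibration.** Photographs carry no scale, but the adult white-to-white
corneal diameter is nearly constant, 11.71 ± 0.42 mm. With the limbus
annotated, each photo's scale is

    s = 11.71 mm / d_px        (d_px = limbus-to-limbus distance in pixels,
                                averaged over the measurable eyes)

and every pixel distance converts to millimetres per face, with no
cross-photo scale sharing.

**Pose.** The in-plane head rotation is the signed angle between the
glabella→menton midline and the image vertical (positive = clockwise).
Distances need no rotation correction; angles measured against the image
horizontal (canthal tilt) are corrected by the rotation angle, and eyebrow
angles are measured against the interpupillary line, which makes them
tilt-invariant by construction.

**Battery.** Core facial heights/widths (trichion–menton, bizygomatic,
bigonial, …), seven forehead heights FH M1–M7 (hairline to eyebrow),
periorbital distances, eyebrow lengths and the three brow angles, canthal
tilt, nasal dimensions, and the thirteen subnasale→contour distances
M1–M13. Bilateral quantities are reported per side and averaged. Facial
proportions R1–R10 (e.g. R5 = facial height : bigonial width, compared
against the golden ratio 1.618), horizontal facial thirds
(upper : mid : lower, upper = 1) and vertical thirds
(right : intercanthal : left, outer mean = 1) follow. Group comparison uses
Welch's t-test by default (Mann-Whitney selectable, exact null for small
tie-free samples), sample SDs with n−1, no multiple-testing correction.

**Contours.** The facial outline is the 24 landmarks (9 hairline, 2 zygoma,
13 jawline); faces are aligned by subnasale translation plus midline
de-rotation — deliberately without size normalisation, since absolute size
differences between groups are a finding — and averaged pointwise.

## Worked example

```python
import numpy as np
from facemorph import (GeneratorParams, generate_face, measure_face,
                       compute_ratios, calibrate_face)

params = GeneratorParams(group="female")           # reference-table presets
ls = generate_face(params, np.random.default_rng(7))
rec = measure_face(ls)                             # pixel -> mm -> battery
rr = compute_ratios(rec, calibrate_face(ls))
```

prints, via the fields of `rec` and `rr`:

```
facial height         19.12 cm
bigonial width        10.70 cm
interpupillary dist.   6.00 cm
canthal tilt           7.18 deg
face rotation          0.27 deg
R5 height:bigonial     1.79
horizontal thirds     1:1.18:1.05
```

— one sampled face: 19.12 cm trichion→menton, a slightly narrow jaw for its
height (R5 above the golden ratio), a typical feminine upward canthal tilt,
and a 0.27° residual head rotation that the angle corrections absorb.

The same flow is available from a shell:

```
facemorph simulate --group female --n 21 --seed 42 --out-dir f/
facemorph simulate --group male   --n 21 --seed 43 --out-dir m/
facemorph compare --group-a f/ --group-b m/ --out summary.tsv
facemorph contour --group-a f/ --group-b m/ --out-prefix contours
```

## The analysis

`analysis/01…05` run the full study over generated cohorts and write their
tables under `results/`:

1. `01_simulate_cohorts.py` — 21 + 21 landmark files at the table presets;
2. `02_measure_battery.py` — the per-face measurement battery;
3. `03_ratios_and_thirds.py` — proportions and thirds (mean of per-subject
   ratios);
4. `04_sex_dimorphism_stats.py` — the nine summary tables with p-values;
5. `05_mean_contours.py` — the aligned mean-contour overlay.

At seed 42 this reproduces the reference pattern: significant male excess
in facial height, facial width, lower facial height, bigonial width, the
lateral forehead heights, total brow length, nose length and alar width and
in all thirteen lower-face distances; no periorbital dimorphism; a flatter
medial brow in males (brow angle 1); both sexes' R5 within 0.02 of the
golden ratio; and a male mean contour whose menton sits about 1 cm lower.

## Limitations

Frontal 2D analysis only (no profile or 3D), no landmark detection from
pixels, and the generator samples measurements from their marginal
distributions without a covariance model; see `docs/methods.md` for the
full discussion.
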