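"""Reference cohort statistics: gender-specific measurement means and SDs.

These presets encode the printed group statistics (mean, SD; centimetres or
degrees) of a reference cohort of 21 female and 21 male frontal photographs
analysed with this measurement battery.  They drive the synthetic cohort
generator and serve as recovery targets in the tests.

Two internal inconsistencies of the printed tables are handled explicitly:

* The printed glabella→subnasale ("mid facial height") means, 3.53/3.67 cm,
  contradict midline additivity — facial height (19.00/20.40) minus
  forehead height (6.03/5.98) minus lower facial height (6.40/7.53) leaves
  6.57/6.89 cm — and the cohort's own facial-thirds ratios (1:1.09:1.06 and
  1:1.15:1.26) and height:midface ratios (2.90/2.97), all of which are
  consistent with 6.57/6.89.  The printed values are kept verbatim here;
  :func:`generator_targets` derives the additive-consistent value instead.
* The printed female "Avg M3 and M11" row (5.81) disagrees with its own
  components (5.73, 5.60); averages are always recomputed from components.
"""

from __future__ import annotations

N_PER_GROUP = 21

# (female (mean, sd), male (mean, sd)); cm unless listed in ANGULAR_TARGETS
_ROWS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    # core facial dimensions
    "facial_height":        ((19.00, 0.99), (20.40, 1.75)),
    "facial_width":         ((13.63, 0.83), (14.25, 0.99)),
    "forehead_height":      ((6.03, 0.61), (5.98, 0.89)),
    "forehead_width":       ((13.56, 0.82), (13.73, 1.01)),
    "mid_facial_height":    ((3.53, 0.29), (3.67, 0.27)),   # printed; see module docstring
    "lower_facial_height":  ((6.40, 0.52), (7.53, 0.79)),
    "bigonial_width":       ((11.61, 0.89), (12.71, 0.98)),
    # forehead heights
    "fh_m1": ((3.20, 0.81), (4.16, 1.41)),
    "fh_m2": ((3.96, 0.68), (5.02, 0.84)),
    "fh_m3": ((6.10, 0.55), (6.07, 0.89)),
    "fh_m4": ((6.03, 0.61), (5.98, 0.89)),
    "fh_m5": ((6.12, 0.54), (5.96, 0.91)),
    "fh_m6": ((3.91, 0.72), (4.84, 0.82)),
    "fh_m7": ((3.23, 0.79), (4.21, 1.44)),
    "avg_fh_m1_m7": ((3.22, 0.79), (4.18, 1.42)),
    "avg_fh_m2_m6": ((3.94, 0.70), (4.93, 0.82)),
    "avg_fh_m3_m5": ((6.11, 0.54), (6.01, 0.90)),
    # periorbital
    "palpebral_fissure_height_l": ((0.96, 0.09), (0.95, 0.10)),
    "palpebral_fissure_height_r": ((0.95, 0.09), (0.97, 0.10)),
    "palpebral_fissure_width_l":  ((2.79, 0.14), (2.86, 0.24)),
    "palpebral_fissure_width_r":  ((2.79, 0.14), (2.86, 0.23)),
    "interpupillary_distance":    ((6.59, 0.39), (6.75, 0.48)),
    # eyebrow lengths and brow-canthus distances
    "medial_brow_len_l":  ((3.11, 0.28), (3.28, 0.42)),
    "medial_brow_len_r":  ((3.16, 0.29), (3.34, 0.33)),
    "medial_brow_len_avg": ((3.13, 0.25), (3.31, 0.35)),
    "lateral_brow_len_l": ((1.73, 0.26), (1.89, 0.32)),
    "lateral_brow_len_r": ((1.73, 0.26), (1.85, 0.40)),
    "lateral_brow_len_avg": ((1.73, 0.23), (1.87, 0.31)),
    "total_brow_len_l":   ((4.85, 0.37), (5.17, 0.59)),
    "total_brow_len_r":   ((4.88, 0.39), (5.19, 0.49)),
    "total_brow_len_avg": ((4.87, 0.35), (5.18, 0.52)),
    "lat_brow_to_lat_canthus_avg": ((2.02, 0.22), (1.87, 0.21)),
    "med_brow_to_med_canthus_avg": ((2.35, 0.29), (2.38, 0.58)),
    # angles (degrees)
    "brow_angle_1": ((12.01, 4.99), (8.07, 6.39)),
    "brow_angle_2": ((54.99, 8.12), (55.32, 6.38)),
    "brow_angle_3": ((42.8, 8.84), (47.25, 6.38)),
    "canthal_tilt": ((7.49, 2.86), (5.93, 2.27)),
    # nose
    "nose_length": ((3.91, 0.44), (4.27, 0.47)),
    "alar_width":  ((3.93, 0.41), (4.44, 0.64)),
    # lower face (subnasale to contour point k)
    "m1":  ((6.40, 0.55), (6.78, 0.53)),
    "m2":  ((5.96, 0.60), (6.59, 0.59)),
    "m3":  ((5.73, 0.57), (6.56, 0.66)),
    "m4":  ((6.01, 0.56), (7.12, 0.76)),
    "m5":  ((6.25, 0.52), (7.45, 0.77)),
    "m6":  ((6.37, 0.50), (7.53, 0.79)),
    "m7":  ((6.40, 0.52), (7.53, 0.79)),
    "m8":  ((6.40, 0.50), (7.55, 0.81)),
    "m9":  ((6.31, 0.51), (7.49, 0.82)),
    "m10": ((6.09, 0.53), (7.20, 0.79)),
    "m11": ((5.60, 0.55), (6.70, 0.73)),
    "m12": ((6.19, 0.45), (6.87, 0.67)),
    "m13": ((6.59, 0.47), (7.06, 0.60)),
    "avg_m1_m13": ((6.49, 0.45), (6.92, 0.51)),
    "avg_m2_m12": ((6.08, 0.48), (6.73, 0.59)),
    "avg_m3_m11": ((5.81, 0.53), (6.63, 0.68)),   # female row inconsistent; see docstring
    "avg_m4_m10": ((6.05, 0.54), (7.16, 0.77)),
    "avg_m5_m9":  ((6.28, 0.51), (7.47, 0.79)),
    "avg_m6_m8":  ((6.39, 0.50), (7.54, 0.80)),
}

ANGULAR_TARGETS = ("brow_angle_1", "brow_angle_2", "brow_angle_3", "canthal_tilt")

FEMALE_TABLES: dict[str, tuple[float, float]] = {k: v[0] for k, v in _ROWS.items()}
MALE_TABLES: dict[str, tuple[float, float]] = {k: v[1] for k, v in _ROWS.items()}

#: printed cohort proportion means (mean, sd), dimensionless
PRINTED_RATIOS = {
    "female": {
        "r1": (1.40, 0.068), "r2": (0.45, 0.05), "r3": (0.55, 0.04),
        "r4": (3.17, 0.26), "r5": (1.64, 0.10), "r6": (1.01, 0.03),
        "r7": (1.18, 0.04), "r8": (1.17, 0.06), "r9": (3.17, 0.26),
        "r10": (2.90, 0.16),
    },
    "male": {
        "r1": (1.43, 0.087), "r2": (0.44, 0.06), "r3": (0.59, 0.04),
        "r4": (3.45, 0.38), "r5": (1.61, 0.08), "r6": (1.04, 0.03),
        "r7": (1.12, 0.05), "r8": (1.08, 0.05), "r9": (3.45, 0.38),
        "r10": (2.97, 0.21),
    },
}

#: printed facial-thirds triples
PRINTED_THIRDS = {
    "female": {"horizontal": (1.0, 1.09, 1.06), "vertical": (1.0, 1.27, 1.0)},
    "male": {"horizontal": (1.0, 1.15, 1.26), "vertical": (1.0, 1.29, 1.0)},
}

#: reported accuracy of the photo-calibration workflow against a ruler
VALIDATION_MAE_MM = 1.17
VALIDATION_MAE_SD_MM = 1.14

#: reported bony mandibular widths used for the power computation, cm
POWER_EXAMPLE = {"male": (9.35, 0.57), "female": (8.70, 0.56)}

#: rows that are averages of other rows — never sampled by the generator
_DERIVED = tuple(k for k in _ROWS if k.startswith("avg_")) + (
    "medial_brow_len_avg", "lateral_brow_len_avg", "total_brow_len_avg",
    "total_brow_len_l", "total_brow_len_r",   # total = medial + lateral
    "fh_m4",            # identical to forehead_height (trichion–glabella)
    "m7",               # identical to lower_facial_height (subnasale–menton)
    "mid_facial_height",  # derived additively, see module docstring
    "brow_angle_2",     # emergent: angle 1 + angle 3 for straight brow lines
)


def table_for(group) -> dict[str, tuple[float, float]]:
    g = getattr(group, "value", group)
    if g == "female":
        return FEMALE_TABLES
    if g == "male":
        return MALE_TABLES
    raise ValueError(f"no preset tables for group {g!r}")


def generator_targets(group) -> dict[str, tuple[float, float]]:
    """The independently sampled generator targets for one group.

    Derived rows (averages, aliases, and the additively determined mid
    facial height) are excluded; the generator reproduces them by
    construction.
    """
    table = table_for(group)
    return {k: v for k, v in table.items() if k not in _DERIVED}


def derived_mid_facial_height(group) -> float:
    """Additive-consistent glabella→subnasale height (cm) for a group's means."""
    t = table_for(group)
    return t["facial_height"][0] - t["forehead_height"][0] - t["lower_facial_height"][0]
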