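"""The measurement battery: worked values, identities, and invariances."""

import math

import numpy as np
import pytest

from facemorph.errors import MissingLandmarkError
from facemorph.landmarks_io import LandmarkSet
from facemorph.measurements import (
    ALL_FIELDS,
    ANGULAR_FIELDS,
    LINEAR_FIELDS,
    brow_angles,
    distance,
    forehead_measurements,
    lower_face_measurements,
    measure_face,
    nasal_measurements,
    periorbital_measurements,
)
from facemorph.pose import PoseInfo

from util import make_ls, metric_face


def test_distance_345_triangle_and_symmetry():
    assert distance((0.0, 0.0), (30.0, 40.0)) == pytest.approx(5.0)
    assert distance((3.0, 4.0), (3.0, 4.0)) == 0.0
    assert distance((1.0, 2.0), (-7.0, 9.0)) == distance((-7.0, 9.0), (1.0, 2.0))


def test_core_measurements_recover_reference_means(mean_records):
    rec = mean_records["female"]
    assert rec.facial_height == pytest.approx(19.00, rel=1e-6)
    assert rec.bigonial_width == pytest.approx(11.61, rel=1e-6)
    rec_m = mean_records["male"]
    assert rec_m.facial_height == pytest.approx(20.40, rel=1e-6)
    assert rec_m.lower_facial_height == pytest.approx(7.53, rel=1e-6)


def test_translation_invariance(mean_faces):
    ls, _ = mean_faces["female"]
    shifted = LandmarkSet(ls.subject_id, ls.group,
                          {n: (x + 50.0, y - 30.0) for n, (x, y) in ls.points.items()})
    a, b = measure_face(ls), measure_face(shifted)
    for f in ALL_FIELDS:
        assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-9, abs=1e-9)


def test_collinear_midline_thirds_are_additive(mean_records):
    """Trichion, glabella, subnasale and menton on one vertical line."""
    for rec in mean_records.values():
        total = rec.forehead_height + rec.mid_facial_height + rec.lower_facial_height
        assert total == pytest.approx(rec.facial_height, rel=1e-9)


def test_forehead_axis_aligned_example():
    pts = {
        "HL_p2": (-40.0, 60.0), "EB_p1": (-40.0, 20.0),
        "HL_p3": (-30.0, 62.0), "EB_p2": (-30.0, 25.0),
        "HL_p4": (-15.0, 64.0), "EB_p3": (-15.0, 28.0),
        "HL_p5": (0.0, 126.0), "GLABELLA": (0.0, 66.0),
        "HL_p6": (15.0, 64.0), "EB_p4": (15.0, 28.0),
        "HL_p7": (30.0, 62.0), "EB_p5": (30.0, 25.0),
        "HL_p8": (40.0, 60.0), "EB_p6": (40.0, 20.0),
    }
    fh = forehead_measurements(metric_face(pts))
    assert fh["fh_m1"] == pytest.approx(4.0)
    assert fh["fh_m4"] == pytest.approx(6.0)
    assert fh["fh_m1"] == fh["fh_m7"] and fh["fh_m2"] == fh["fh_m6"]
    assert fh["avg_fh_m1_m7"] == pytest.approx(4.0)


def test_periorbital_construction_values():
    pts = {
        "LID_UP_R": (-33.0, 9.6), "LID_LO_R": (-33.0, 0.0),
        "LID_UP_L": (33.0, 9.6), "LID_LO_L": (33.0, 0.0),
        "EX_R": (-47.0, 1.0), "EN_R": (-19.1, 0.0),
        "EN_L": (19.1, 0.0), "EX_L": (47.0, 1.0),
        "IRIS_R": (-33.75, 4.0), "IRIS_L": (33.75, 4.0),
    }
    peri = periorbital_measurements(metric_face(pts))
    assert peri["palpebral_fissure_height_r"] == pytest.approx(0.96)
    assert peri["interpupillary_distance"] == pytest.approx(6.75)
    # both eyes identical by construction -> average equals either side
    assert peri["palpebral_fissure_height_avg"] == peri["palpebral_fissure_height_r"]


def test_brow_total_is_sum_and_degenerate_lateral(mean_records):
    rec = mean_records["female"]
    assert rec.total_brow_len_l == rec.medial_brow_len_l + rec.lateral_brow_len_l
    assert rec.total_brow_len_r == rec.medial_brow_len_r + rec.lateral_brow_len_r

    from facemorph.measurements import brow_measurements
    pts = {
        "EB_p3": (-15.0, 30.0), "EB_p2": (-45.0, 36.0), "EB_p1": (-45.0, 36.0),
        "EB_p4": (15.0, 30.0), "EB_p5": (45.0, 36.0), "EB_p6": (45.0, 36.0),
        "EX_R": (-47.0, 4.0), "EN_R": (-19.0, 0.0),
        "EN_L": (19.0, 0.0), "EX_L": (47.0, 4.0),
    }
    out = brow_measurements(metric_face(pts))
    assert out["lateral_brow_len_r"] == 0.0
    assert out["total_brow_len_r"] == out["medial_brow_len_r"]


def _brow_geometry(a1_deg: float, a3_deg: float) -> dict:
    """Symmetric brows with medial lines at +a1 and lateral lines at -a3."""
    a1, a3 = math.radians(a1_deg), math.radians(a3_deg)
    pts = {"IRIS_R": (-33.0, 0.0), "IRIS_L": (33.0, 0.0)}
    for sign, med, peak, lat in ((-1, "EB_p3", "EB_p2", "EB_p1"),
                                 (1, "EB_p4", "EB_p5", "EB_p6")):
        m = np.array([sign * 15.0, 25.0])  # medial brow point
        p = m + 31.3 * np.array([sign * math.cos(a1), math.sin(a1)])
        l = p + 17.3 * np.array([sign * math.cos(a3), -math.sin(a3)])
        pts[med], pts[peak], pts[lat] = m, p, l
    return pts


def test_brow_angles_match_construction_and_sum_identity():
    pts = _brow_geometry(12.01, 42.8)
    face = metric_face(pts)
    out = brow_angles(face, PoseInfo(0.0, np.array([1.0, 0.0])))
    assert out["brow_angle_1"] == pytest.approx(12.01, abs=1e-9)
    assert out["brow_angle_3"] == pytest.approx(42.8, abs=1e-9)
    # with straight brow lines, angle 2 is the sum of the two elevations
    assert out["brow_angle_2"] == pytest.approx(12.01 + 42.8, abs=1e-9)


def test_brow_collinear_with_axis_is_zero_angle1():
    pts = _brow_geometry(0.0, 40.0)
    out = brow_angles(metric_face(pts), PoseInfo(0.0, np.array([1.0, 0.0])))
    assert out["brow_angle_1"] == pytest.approx(0.0, abs=1e-12)


def test_nasal_construction_values():
    pts = {"NASION": (0.0, 45.0), "PRONASALE": (0.0, 5.9),
           "ALA_R": (-19.65, 0.0), "ALA_L": (19.65, 0.0)}
    out = nasal_measurements(metric_face(pts))
    assert out["alar_width"] == pytest.approx(3.93)
    assert out["nose_length"] == pytest.approx(3.91)
    pts["PRONASALE"] = pts["NASION"]
    assert nasal_measurements(metric_face(pts))["nose_length"] == 0.0


def test_lower_face_m7_equals_lower_facial_height(mean_records):
    pts = {"SUBNASALE": (0.0, 0.0), **{f"P{k}": (float(7 - k) * 8.0, -50.0)
                                       for k in range(1, 14)}}
    pts["P7"] = (0.0, -64.0)
    out = lower_face_measurements(metric_face(pts))
    assert out["m7"] == pytest.approx(6.40)
    for rec in mean_records.values():
        assert rec.m7 == rec.lower_facial_height  # identical landmarks, bitwise


def test_mirror_symmetry_swaps_sides_and_preserves_averages(mean_faces):
    """x-negation plus side relabelling swaps sided fields and leaves every
    averaged or midline field unchanged (the rotation sign flips by design)."""
    ls, _ = mean_faces["male"]
    a, b = measure_face(ls), measure_face(ls.mirrored())
    swapped = (
        [(f"fh_m{i}", f"fh_m{8 - i}") for i in (1, 2, 3)]
        + [(f"m{k}", f"m{14 - k}") for k in range(1, 7)]
        + [(f"{stem}_l", f"{stem}_r") for stem in
           ("palpebral_fissure_height", "palpebral_fissure_width",
            "medial_brow_len", "lateral_brow_len", "total_brow_len")]
    )
    sided = {n for pair in swapped for n in pair}
    for x, y in swapped:
        assert getattr(a, x) == pytest.approx(getattr(b, y), rel=1e-9), (x, y)
    for f in ALL_FIELDS:
        if f in sided or f == "face_rotation_deg":
            continue
        assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-9, abs=1e-9), f
    assert a.face_rotation_deg == pytest.approx(-b.face_rotation_deg, abs=1e-9)


def test_measure_face_partial_battery(mean_faces):
    ls, _ = mean_faces["female"]
    pts = {n: p for n, p in ls.points.items() if not n.startswith("HL_")}
    rec = measure_face(LandmarkSet(ls.subject_id, ls.group, pts))
    assert rec.facial_width is not None
    assert rec.fh_m1 is None and rec.facial_height is None  # trichion is HL_p5
    assert rec.m5 is not None


def test_complete_face_has_no_missing_fields(mean_records):
    for rec in mean_records.values():
        for f in ALL_FIELDS:
            assert getattr(rec, f) is not None, f


def test_record_invariants_on_synthetic_cohort(default_cohorts):
    for ls in default_cohorts["female"]:
        rec = measure_face(ls)
        for f in LINEAR_FIELDS:
            assert getattr(rec, f) >= 0.0
        assert rec.palpebral_fissure_width_avg == pytest.approx(
            0.5 * (rec.palpebral_fissure_width_l + rec.palpebral_fissure_width_r))
        assert rec.avg_m2_m12 == pytest.approx(0.5 * (rec.m2 + rec.m12))
        assert rec.m7 == rec.lower_facial_height


def test_block_functions_raise_on_missing_landmark(mean_faces):
    ls, _ = mean_faces["female"]
    pts = {n: p for n, p in ls.points.items() if n != "NASION"}
    from facemorph.calibration import calibrate_face
    face = calibrate_face(LandmarkSet(points=pts))
    with pytest.raises(MissingLandmarkError, match="NASION"):
        nasal_measurements(face)
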