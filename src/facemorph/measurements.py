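"""The frontal facial measurement battery.

Evaluates, on one calibrated face, the full set of named linear (cm) and
angular (degree) measurements used by the cohort analysis: core facial
dimensions, the seven forehead heights FH M1–M7, periorbital distances,
eyebrow lengths and angles, canthal tilt, nasal dimensions, and the
thirteen subnasale→contour distances M1–M13.  Internal computation is in
millimetres at full precision; linear results are reported in centimetres.

Left/right measurements are also returned averaged, following the cohort
convention that bilateral quantities enter the analysis as the mean of the
two sides.  ``measure_face`` fills what the available landmarks allow and
leaves the rest ``None``; the per-block functions raise
:class:`~facemorph.errors.MissingLandmarkError` instead.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from . import pose as _pose
from .calibration import REFERENCE_CORNEAL_MM, CalibratedFace, calibrate_face
from .errors import DegenerateGeometryError, MissingLandmarkError
from .landmarks_io import LandmarkSet

CORE_FIELDS = (
    "facial_height", "facial_width", "forehead_height", "forehead_width",
    "mid_facial_height", "lower_facial_height", "bigonial_width",
)
FOREHEAD_FIELDS = tuple(f"fh_m{i}" for i in range(1, 8)) + (
    "avg_fh_m1_m7", "avg_fh_m2_m6", "avg_fh_m3_m5",
)
PERIORBITAL_FIELDS = (
    "palpebral_fissure_height_l", "palpebral_fissure_height_r", "palpebral_fissure_height_avg",
    "palpebral_fissure_width_l", "palpebral_fissure_width_r", "palpebral_fissure_width_avg",
    "interpupillary_distance",
)
BROW_FIELDS = (
    "medial_brow_len_l", "medial_brow_len_r", "medial_brow_len_avg",
    "lateral_brow_len_l", "lateral_brow_len_r", "lateral_brow_len_avg",
    "total_brow_len_l", "total_brow_len_r", "total_brow_len_avg",
    "lat_brow_to_lat_canthus_avg", "med_brow_to_med_canthus_avg",
)
ANGLE_FIELDS = ("brow_angle_1", "brow_angle_2", "brow_angle_3", "canthal_tilt")
NASAL_FIELDS = ("nose_length", "alar_width")
LOWER_FACE_FIELDS = tuple(f"m{i}" for i in range(1, 14)) + (
    "avg_m1_m13", "avg_m2_m12", "avg_m3_m11", "avg_m4_m10", "avg_m5_m9", "avg_m6_m8",
)

#: Every field of a MeasurementRecord, in report order.
ALL_FIELDS = (
    CORE_FIELDS + FOREHEAD_FIELDS + PERIORBITAL_FIELDS + BROW_FIELDS
    + ANGLE_FIELDS + NASAL_FIELDS + LOWER_FACE_FIELDS + ("face_rotation_deg",)
)

#: Fields measured in degrees; every other field is in centimetres.
ANGULAR_FIELDS = ANGLE_FIELDS + ("face_rotation_deg",)
LINEAR_FIELDS = tuple(f for f in ALL_FIELDS if f not in ANGULAR_FIELDS)

MeasurementRecord = dataclasses.make_dataclass(
    "MeasurementRecord",
    [(name, "float | None", dataclasses.field(default=None)) for name in ALL_FIELDS],
    namespace={
        "as_dict": lambda self: dataclasses.asdict(self),
        "__doc__": (
            "The named measurement battery for one face; ``None`` marks a "
            "measurement whose landmarks were unavailable.  Linear fields are "
            "centimetres, angular fields degrees."
        ),
    },
)


def distance(p, q) -> float:
    """Euclidean distance between two metric (mm) points, reported in cm."""
    return math.dist(np.asarray(p, float), np.asarray(q, float)) / 10.0


def _d(face: CalibratedFace, a: str, b: str) -> float:
    face_points = face.points
    missing = [n for n in (a, b) if n not in face_points]
    if missing:
        raise MissingLandmarkError(*missing)
    return distance(face_points[a], face_points[b])


def core_measurements(face: CalibratedFace) -> dict[str, float]:
    """Facial/forehead heights and widths plus bigonial width (Trichion = HL_p5)."""
    return {
        "facial_height": _d(face, "HL_p5", "P7"),
        "facial_width": _d(face, "ZY_R", "ZY_L"),
        "forehead_height": _d(face, "HL_p5", "GLABELLA"),
        "forehead_width": _d(face, "HL_p1", "HL_p9"),
        "mid_facial_height": _d(face, "GLABELLA", "SUBNASALE"),
        "lower_facial_height": _d(face, "SUBNASALE", "P7"),
        "bigonial_width": _d(face, "P2", "P12"),
    }


# hairline point above each eyebrow point, viewer-left to viewer-right
_FOREHEAD_PAIRS = {
    "fh_m1": ("HL_p2", "EB_p1"),
    "fh_m2": ("HL_p3", "EB_p2"),
    "fh_m3": ("HL_p4", "EB_p3"),
    "fh_m4": ("HL_p5", "GLABELLA"),
    "fh_m5": ("HL_p6", "EB_p4"),
    "fh_m6": ("HL_p7", "EB_p5"),
    "fh_m7": ("HL_p8", "EB_p6"),
}


def forehead_measurements(face: CalibratedFace) -> dict[str, float]:
    """Vertical forehead heights FH M1–M7 and their mirror-pair averages."""
    out = {k: _d(face, a, b) for k, (a, b) in _FOREHEAD_PAIRS.items()}
    out["avg_fh_m1_m7"] = 0.5 * (out["fh_m1"] + out["fh_m7"])
    out["avg_fh_m2_m6"] = 0.5 * (out["fh_m2"] + out["fh_m6"])
    out["avg_fh_m3_m5"] = 0.5 * (out["fh_m3"] + out["fh_m5"])
    return out


def periorbital_measurements(face: CalibratedFace) -> dict[str, float]:
    out = {
        "palpebral_fissure_height_r": _d(face, "LID_UP_R", "LID_LO_R"),
        "palpebral_fissure_height_l": _d(face, "LID_UP_L", "LID_LO_L"),
        "palpebral_fissure_width_r": _d(face, "EX_R", "EN_R"),
        "palpebral_fissure_width_l": _d(face, "EX_L", "EN_L"),
        "interpupillary_distance": _d(face, "IRIS_R", "IRIS_L"),
    }
    out["palpebral_fissure_height_avg"] = 0.5 * (
        out["palpebral_fissure_height_r"] + out["palpebral_fissure_height_l"]
    )
    out["palpebral_fissure_width_avg"] = 0.5 * (
        out["palpebral_fissure_width_r"] + out["palpebral_fissure_width_l"]
    )
    return out


def brow_measurements(face: CalibratedFace) -> dict[str, float]:
    """Medial/lateral/total eyebrow lengths and brow-to-canthus distances.

    Right brow runs EB_p1 (lateral) – EB_p2 (peak) – EB_p3 (medial); the left
    brow mirrors it as EB_p4 (medial) – EB_p5 (peak) – EB_p6 (lateral).
    Total length is medial + lateral by definition (arc length along the
    brow), not the straight end-to-end distance.
    """
    out = {
        "medial_brow_len_r": _d(face, "EB_p3", "EB_p2"),
        "lateral_brow_len_r": _d(face, "EB_p2", "EB_p1"),
        "medial_brow_len_l": _d(face, "EB_p4", "EB_p5"),
        "lateral_brow_len_l": _d(face, "EB_p5", "EB_p6"),
    }
    for side in ("r", "l"):
        out[f"total_brow_len_{side}"] = (
            out[f"medial_brow_len_{side}"] + out[f"lateral_brow_len_{side}"]
        )
    for stem in ("medial_brow_len", "lateral_brow_len", "total_brow_len"):
        out[f"{stem}_avg"] = 0.5 * (out[f"{stem}_r"] + out[f"{stem}_l"])
    out["lat_brow_to_lat_canthus_avg"] = 0.5 * (
        _d(face, "EB_p1", "EX_R") + _d(face, "EB_p6", "EX_L")
    )
    out["med_brow_to_med_canthus_avg"] = 0.5 * (
        _d(face, "EB_p3", "EN_R") + _d(face, "EB_p4", "EN_L")
    )
    return out


def _brow_side_angles(medial, peak, lateral, axis: np.ndarray) -> tuple[float, float, float]:
    """(angle1, angle2, angle3) for one brow against the interpupillary axis."""
    perp = np.array([-axis[1], axis[0]])  # axis rotated 90° CCW: superior direction
    d_med = np.asarray(peak, float) - np.asarray(medial, float)
    d_lat = np.asarray(lateral, float) - np.asarray(peak, float)
    for d, what in ((d_med, "medial"), (d_lat, "lateral")):
        if np.allclose(d, 0.0):
            raise DegenerateGeometryError(f"zero-length {what} brow line")
    # elevation of the medial brow line, positive when the peak is superior
    a1 = math.degrees(math.atan2(float(d_med @ perp), abs(float(d_med @ axis))))
    cos_a2 = float(d_med @ d_lat) / (np.linalg.norm(d_med) * np.linalg.norm(d_lat))
    a2 = math.degrees(math.acos(min(1.0, max(-1.0, cos_a2))))
    a3 = abs(math.degrees(math.atan2(float(d_lat @ perp), abs(float(d_lat @ axis)))))
    return a1, a2, a3


def brow_angles(face: CalibratedFace, pose: _pose.PoseInfo) -> dict[str, float]:
    """The three eyebrow angles, measured against the interpupillary line.

    Angle 1: medial brow line vs. the interpupillary line, positive when the
    brow peak is superior to the medial brow point (an upward-slanting medial
    brow).  Angle 2: between the medial and lateral brow lines.  Angle 3:
    lateral brow line vs. the interpupillary line (unsigned).  Sides averaged.
    Referencing the interpupillary line makes all three invariant to head tilt.
    """
    for name in ("EB_p1", "EB_p2", "EB_p3", "EB_p4", "EB_p5", "EB_p6"):
        if name not in face.points:
            raise MissingLandmarkError(name)
    p = face.points
    right = _brow_side_angles(p["EB_p3"], p["EB_p2"], p["EB_p1"], pose.ipd_axis)
    left = _brow_side_angles(p["EB_p4"], p["EB_p5"], p["EB_p6"], pose.ipd_axis)
    return {
        "brow_angle_1": 0.5 * (right[0] + left[0]),
        "brow_angle_2": 0.5 * (right[1] + left[1]),
        "brow_angle_3": 0.5 * (right[2] + left[2]),
    }


def nasal_measurements(face: CalibratedFace) -> dict[str, float]:
    return {
        "nose_length": _d(face, "NASION", "PRONASALE"),
        "alar_width": _d(face, "ALA_R", "ALA_L"),
    }


def lower_face_measurements(face: CalibratedFace) -> dict[str, float]:
    """Subnasale→contour distances M1–M13 and their mirror-pair averages.

    M7 is by construction identical to the lower facial height (both are the
    subnasale→menton distance).
    """
    out = {f"m{k}": _d(face, "SUBNASALE", f"P{k}") for k in range(1, 14)}
    for k in range(1, 7):
        out[f"avg_m{k}_m{14 - k}"] = 0.5 * (out[f"m{k}"] + out[f"m{14 - k}"])
    return out


# every plain two-point distance field and its landmarks, for partial batteries
_DISTANCE_FIELDS: dict[str, tuple[str, str]] = {
    "facial_height": ("HL_p5", "P7"),
    "facial_width": ("ZY_R", "ZY_L"),
    "forehead_height": ("HL_p5", "GLABELLA"),
    "forehead_width": ("HL_p1", "HL_p9"),
    "mid_facial_height": ("GLABELLA", "SUBNASALE"),
    "lower_facial_height": ("SUBNASALE", "P7"),
    "bigonial_width": ("P2", "P12"),
    **_FOREHEAD_PAIRS,
    "palpebral_fissure_height_r": ("LID_UP_R", "LID_LO_R"),
    "palpebral_fissure_height_l": ("LID_UP_L", "LID_LO_L"),
    "palpebral_fissure_width_r": ("EX_R", "EN_R"),
    "palpebral_fissure_width_l": ("EX_L", "EN_L"),
    "interpupillary_distance": ("IRIS_R", "IRIS_L"),
    "medial_brow_len_r": ("EB_p3", "EB_p2"),
    "lateral_brow_len_r": ("EB_p2", "EB_p1"),
    "medial_brow_len_l": ("EB_p4", "EB_p5"),
    "lateral_brow_len_l": ("EB_p5", "EB_p6"),
    "nose_length": ("NASION", "PRONASALE"),
    "alar_width": ("ALA_R", "ALA_L"),
    **{f"m{k}": ("SUBNASALE", f"P{k}") for k in range(1, 14)},
}

# average/sum fields and their constituents
_COMPOSITE_FIELDS: dict[str, tuple[str, ...]] = {
    "total_brow_len_r": ("medial_brow_len_r", "lateral_brow_len_r"),
    "total_brow_len_l": ("medial_brow_len_l", "lateral_brow_len_l"),
    "avg_fh_m1_m7": ("fh_m1", "fh_m7"),
    "avg_fh_m2_m6": ("fh_m2", "fh_m6"),
    "avg_fh_m3_m5": ("fh_m3", "fh_m5"),
    "palpebral_fissure_height_avg": ("palpebral_fissure_height_l", "palpebral_fissure_height_r"),
    "palpebral_fissure_width_avg": ("palpebral_fissure_width_l", "palpebral_fissure_width_r"),
    "medial_brow_len_avg": ("medial_brow_len_l", "medial_brow_len_r"),
    "lateral_brow_len_avg": ("lateral_brow_len_l", "lateral_brow_len_r"),
    "total_brow_len_avg": ("total_brow_len_l", "total_brow_len_r"),
    **{f"avg_m{k}_m{14 - k}": (f"m{k}", f"m{14 - k}") for k in range(1, 7)},
}


def measure_face(
    ls: LandmarkSet,
    cal=None,
    reference_mm: float = REFERENCE_CORNEAL_MM,
):
    """Run the full battery on one landmark set.

    Calibration is derived from the face's own limbus points unless ``cal``
    is supplied.  Fields whose landmarks are absent are left ``None`` (not
    zero) so partial batteries remain usable; field-level granularity means
    e.g. a missing hairline blanks the forehead heights but not the widths.
    """
    from .calibration import to_metric  # local import to keep module load light

    face = to_metric(ls, cal) if cal is not None else calibrate_face(ls, reference_mm)
    p = face.points
    values: dict[str, float] = {}
    for f, (a, b) in _DISTANCE_FIELDS.items():
        if a in p and b in p:
            values[f] = distance(p[a], p[b])
    for f, parts in _COMPOSITE_FIELDS.items():
        if all(c in values for c in parts):
            total = sum(values[c] for c in parts)
            # per-side totals are sums (arc length); everything else averages
            values[f] = total if f in ("total_brow_len_r", "total_brow_len_l") else total / len(parts)
    if p.keys() >= {"EB_p1", "EX_R", "EB_p6", "EX_L"}:
        values["lat_brow_to_lat_canthus_avg"] = 0.5 * (
            distance(p["EB_p1"], p["EX_R"]) + distance(p["EB_p6"], p["EX_L"]))
    if p.keys() >= {"EB_p3", "EN_R", "EB_p4", "EN_L"}:
        values["med_brow_to_med_canthus_avg"] = 0.5 * (
            distance(p["EB_p3"], p["EN_R"]) + distance(p["EB_p4"], p["EN_L"]))
    if face.rotation_deg is not None:
        values["face_rotation_deg"] = face.rotation_deg
        if face.points.keys() >= {"EN_R", "EX_R", "EN_L", "EX_L"}:
            pose = _pose.PoseInfo(face.rotation_deg, np.array([1.0, 0.0]))
            values["canthal_tilt"] = _pose.corrected_canthal_tilt(face, pose)
    if {"IRIS_R", "IRIS_L"} <= face.points.keys():
        try:
            axis = _pose.interpupillary_axis(face.points["IRIS_R"], face.points["IRIS_L"])
            pose = _pose.PoseInfo(face.rotation_deg or 0.0, axis)
            values.update(brow_angles(face, pose))
        except MissingLandmarkError:
            pass
    return MeasurementRecord(**values)


def records_to_frame(records) -> pd.DataFrame:
    """Stack MeasurementRecords into a DataFrame (one row per face)."""
    return pd.DataFrame([r.as_dict() for r in records], columns=list(ALL_FIELDS)).astype(float)


def record_to_tsv(record, path, rounding: int = 2) -> None:
    """Write one record as TSV: measurement, left, right, average, units."""
    sided: dict[str, dict[str, float]] = {}
    rows = []
    d = record.as_dict()
    for name in ALL_FIELDS:
        if name.endswith(("_l", "_r", "_avg")):
            stem, _, side = name.rpartition("_")
            sided.setdefault(stem, {})[side] = d[name]
        else:
            units = "degrees" if name in ANGULAR_FIELDS else "cm"
            rows.append((name, None, None, d[name], units))
    for stem, vals in sided.items():
        rows.append((stem, vals.get("l"), vals.get("r"), vals.get("avg"), "cm"))

    def fmt(v):
        return "" if v is None else f"{v:.{rounding}f}"

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("measurement\tleft\tright\taverage\tunits\n")
        for name, left, right, avg, units in rows:
            fh.write(f"{name}\t{fmt(left)}\t{fmt(right)}\t{fmt(avg)}\t{units}\n")


def record_from_tsv(path):
    """Read back a record written by :func:`record_to_tsv`."""
    frame = pd.read_csv(path, sep="\t")
    values: dict[str, float] = {}
    for _, row in frame.iterrows():
        stem = row["measurement"]
        if stem in ALL_FIELDS:
            if not pd.isna(row["average"]):
                values[stem] = float(row["average"])
            continue
        for col, suffix in (("left", "_l"), ("right", "_r"), ("average", "_avg")):
            name = f"{stem}{suffix}"
            if name in ALL_FIELDS and not pd.isna(row[col]):
                values[name] = float(row[col])
    return MeasurementRecord(**values)
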