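"""Head pose in the image plane: rotation angle, interpupillary axis, canthal tilt.

All functions here operate on *metric* coordinates (mm, y increasing upward).
The signed face-rotation angle is the angle between the glabella→menton
midline and the downward vertical; it is positive when the face is turned
clockwise as seen by the viewer.  Angles measured against the interpupillary
axis are intrinsically invariant to head tilt; the canthal tilt is measured
against the image horizontal and therefore carries an explicit rotation
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, MissingLandmarkError


@dataclass(frozen=True)
class PoseInfo:
    rotation_deg: float
    ipd_axis: np.ndarray  # unit vector, right iris -> left iris, metric frame


def face_rotation_angle(glabella, menton) -> float:
    """Signed in-plane rotation (degrees), positive = clockwise in the image.

    ``glabella`` and ``menton`` are metric (y-up) points.  An upright face
    has the menton straight below the glabella and returns 0; a face whose
    chin has swung toward the viewer's left (clockwise head tilt) returns a
    positive angle.
    """
    v = np.asarray(menton, float) - np.asarray(glabella, float)
    if np.allclose(v, 0.0):
        raise DegenerateGeometryError("glabella and menton coincide")
    # downward vertical is (0, -1) in y-up coordinates
    return math.degrees(math.atan2(-v[0], -v[1]))


def interpupillary_axis(iris_r, iris_l) -> np.ndarray:
    """Unit vector from the right to the left iris center (metric frame)."""
    v = np.asarray(iris_l, float) - np.asarray(iris_r, float)
    n = float(np.hypot(*v))
    if n == 0.0:
        raise DegenerateGeometryError("iris centers coincide")
    return v / n


def estimate_pose(face) -> PoseInfo:
    """PoseInfo from a calibrated face (needs GLABELLA, P7 and both irises)."""
    pts = face.points
    for name in ("GLABELLA", "P7", "IRIS_R", "IRIS_L"):
        if name not in pts:
            raise MissingLandmarkError(name)
    return PoseInfo(
        rotation_deg=face_rotation_angle(pts["GLABELLA"], pts["P7"]),
        ipd_axis=interpupillary_axis(pts["IRIS_R"], pts["IRIS_L"]),
    )


def _eye_elevation(en, ex, lateral_sign: float) -> float:
    """Elevation (deg) of the endocanthion→exocanthion line above horizontal.

    ``lateral_sign`` is the sign of x in the lateral direction for that eye
    (+1 left eye, -1 right eye); positive result = lateral canthus superior.
    """
    d = np.asarray(ex, float) - np.asarray(en, float)
    if np.allclose(d, 0.0):
        raise DegenerateGeometryError("endocanthion and exocanthion coincide")
    return math.degrees(math.atan2(d[1], lateral_sign * d[0]))


def corrected_canthal_tilt(face, pose: PoseInfo) -> float:
    """Rotation-corrected mean canthal tilt (degrees, lateral-superior positive).

    Per eye the canthal line's elevation above the image horizontal is taken
    along the medial→lateral direction; the face-rotation angle enters with
    opposite sign for the two eyes (a clockwise head tilt raises the viewer's
    right canthal line and lowers the left one), which makes the average
    invariant to rigid rotation of the photograph.
    """
    pts = face.points
    for name in ("EN_R", "EX_R", "EN_L", "EX_L"):
        if name not in pts:
            raise MissingLandmarkError(name)
    rot = pose.rotation_deg
    tilt_r = _eye_elevation(pts["EN_R"], pts["EX_R"], -1.0) - rot
    tilt_l = _eye_elevation(pts["EN_L"], pts["EX_L"], +1.0) + rot
    return 0.5 * (tilt_r + tilt_l)


def rotation_matrix_clockwise(deg: float) -> np.ndarray:
    """Matrix applying a viewer-clockwise image rotation to metric (y-up) points."""
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, s], [-s, c]])
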