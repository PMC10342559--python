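"""Pixel→millimetre calibration via the white-to-white corneal diameter.

The horizontal visible iris diameter (limbus to limbus) is remarkably
constant across adults, 11.71 ± 0.42 mm, which makes it an intrinsic metric
ruler present in every frontal photograph: the scale of a photo is
``reference_mm / corneal_diameter_px``.  Calibration is strictly per face;
no scale is shared between photographs.  The ±0.42 mm population spread of
the reference diameter is not propagated into point estimates (documented
caveat, see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import pose as _pose
from .errors import DegenerateGeometryError, MissingLandmarkError
from .landmarks_io import Group, LandmarkSet

#: Accepted mean adult white-to-white corneal diameter, mm.
REFERENCE_CORNEAL_MM = 11.71


@dataclass(frozen=True)
class Calibration:
    corneal_diameter_px: float
    reference_corneal_mm: float = REFERENCE_CORNEAL_MM

    def __post_init__(self) -> None:
        if not self.corneal_diameter_px > 0:
            raise DegenerateGeometryError("corneal diameter must be positive")

    @property
    def scale(self) -> float:
        """mm per pixel."""
        return self.reference_corneal_mm / self.corneal_diameter_px


@dataclass
class CalibratedFace:
    """Landmarks in millimetres (y increasing upward) plus calibration metadata."""

    subject_id: str
    group: Group
    points: dict[str, np.ndarray]
    scale_mm_per_px: float
    rotation_deg: float | None = None  # None when glabella/menton are absent


def corneal_diameter(ls: LandmarkSet) -> float:
    """White-to-white corneal diameter in pixels (mean of the measurable eyes)."""
    diameters = []
    for side in ("R", "L"):
        med, lat = f"LIMBUS_MED_{side}", f"LIMBUS_LAT_{side}"
        if ls.has(med, lat):
            d = math.dist(ls.points[med], ls.points[lat])
            if d == 0.0:
                raise DegenerateGeometryError(f"zero corneal diameter on side {side}")
            diameters.append(d)
    if not diameters:
        raise MissingLandmarkError("LIMBUS_MED_R/LIMBUS_LAT_R", "LIMBUS_MED_L/LIMBUS_LAT_L")
    return float(np.mean(diameters))


def make_calibration(ls: LandmarkSet, reference_mm: float = REFERENCE_CORNEAL_MM) -> Calibration:
    return Calibration(corneal_diameter(ls), reference_mm)


def to_metric(ls: LandmarkSet, cal: Calibration) -> CalibratedFace:
    """Convert a pixel-space landmark set to millimetres.

    The y axis is flipped so that y increases upward (anatomical superior),
    and the in-plane face-rotation angle is attached when the glabella and
    menton are both present.
    """
    s = cal.scale
    points = {n: np.array([x * s, -y * s]) for n, (x, y) in ls.points.items()}
    rotation = None
    if "GLABELLA" in points and "P7" in points:
        rotation = _pose.face_rotation_angle(points["GLABELLA"], points["P7"])
    return CalibratedFace(
        subject_id=ls.subject_id,
        group=ls.group,
        points=points,
        scale_mm_per_px=s,
        rotation_deg=rotation,
    )


def calibrate_face(ls: LandmarkSet, reference_mm: float = REFERENCE_CORNEAL_MM) -> CalibratedFace:
    """Convenience: measure the corneal diameter and convert in one step."""
    return to_metric(ls, make_calibration(ls, reference_mm))
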