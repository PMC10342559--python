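"""Facial proportions R1–R10 and the horizontal/vertical facial thirds.

R1–R10 are dimensionless ratios of named linear measurements; the
horizontal thirds compare the upper (trichion–glabella), middle
(glabella–subnasale) and lower (subnasale–menton) face heights, and the
vertical thirds compare the right palpebral width, intercanthal distance
and left palpebral width.  Horizontal thirds are normalised to the upper
third; vertical thirds to the mean of the two outer segments, the only
convention that prints a symmetric ``1:x:1`` on real, slightly asymmetric
faces.
"""

from __future__ import annotations

from dataclasses import dataclass

from .calibration import CalibratedFace
from .errors import DegenerateGeometryError, MissingFieldError, MissingLandmarkError
from .measurements import distance

#: ratio name -> (numerator field, denominator field)
RATIO_DEFINITIONS: dict[str, tuple[str, str]] = {
    "r1": ("facial_height", "facial_width"),
    "r2": ("forehead_height", "forehead_width"),
    "r3": ("lower_facial_height", "bigonial_width"),
    "r4": ("facial_height", "forehead_width"),
    "r5": ("facial_height", "bigonial_width"),
    "r6": ("facial_width", "forehead_width"),
    "r7": ("facial_width", "bigonial_width"),
    "r8": ("forehead_width", "bigonial_width"),
    "r9": ("facial_height", "forehead_height"),
    "r10": ("facial_height", "mid_facial_height"),
}

GOLDEN_RATIO = 1.618


@dataclass
class RatioRecord:
    r1: float
    r2: float
    r3: float
    r4: float
    r5: float
    r6: float
    r7: float
    r8: float
    r9: float
    r10: float
    r11: tuple[float, float, float]          # upper:mid:lower, upper = 1
    r12: tuple[float, float, float] | None = None  # right:mid:left, outer mean = 1


def _ratio(m, num: str, den: str) -> float:
    a, b = getattr(m, num), getattr(m, den)
    if a is None or b is None:
        raise MissingFieldError(f"ratio needs {num} and {den}")
    if b == 0:
        raise DegenerateGeometryError(f"zero denominator: {den}")
    return a / b

def horizontal_thirds(m) -> tuple[float, float, float]:
    """(1, mid/upper, lower/upper) from a MeasurementRecord."""
    up, mid, low = m.forehead_height, m.mid_facial_height, m.lower_facial_height
    if None in (up, mid, low):
        raise MissingFieldError("horizontal thirds need the three facial heights")
    if up == 0:
        raise DegenerateGeometryError("zero upper third")
    return (1.0, mid / up, low / up)


def vertical_thirds(face: CalibratedFace) -> tuple[float, float, float]:
    """(right, mid, left) palpebral/intercanthal widths, outer mean normalised to 1."""
    p = face.points
    for name in ("EX_R", "EN_R", "EN_L", "EX_L"):
        if name not in p:
            raise MissingLandmarkError(name)
    right = distance(p["EX_R"], p["EN_R"])
    mid = distance(p["EN_R"], p["EN_L"])
    left = distance(p["EN_L"], p["EX_L"])
    s = 0.5 * (right + left)
    if min(right, mid, left) == 0 or s == 0:
        raise DegenerateGeometryError("degenerate zero segment in vertical thirds")
    return (right / s, mid / s, left / s)


def compute_ratios(m, face: CalibratedFace | None = None) -> RatioRecord:
    """All proportions from one face's MeasurementRecord.

    The vertical thirds need canthus coordinates, so ``r12`` is only filled
    when the calibrated face is supplied.
    """
    vals = {name: _ratio(m, num, den) for name, (num, den) in RATIO_DEFINITIONS.items()}
    return RatioRecord(
        **vals,
        r11=horizontal_thirds(m),
        r12=vertical_thirds(face) if face is not None else None,
    )


def format_triple(triple, decimals: int = 2) -> str:
    """Serialise a thirds triple as ``1:x.xx:y.yy`` style text."""
    return ":".join("1" if v == 1.0 else f"{v:.{decimals}f}" for v in triple)
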