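"""Canonical landmark schema and landmark-file input/output.

The vocabulary names the ~60 anatomical points the measurement battery
references, in image (pixel) coordinates: x to the viewer's right, y
downward, origin at the top-left of the photograph.  Names refer to the
subject's anatomical side (``EN_R`` is the subject's right inner eye corner,
which appears on the *left* half of a frontal photograph).  Two exceptions
follow the viewer's frame because their numbering does: the hairline chain
``HL_p1..HL_p9`` and the lower-face contour chain ``P1..P13`` both run from
the viewer's left to the viewer's right (``HL_p2`` sits above the subject's
right eyebrow; ``P7`` is the menton).

Extra points prefixed ``AUX_`` are accepted and carried through unchanged,
so landmark files from richer detectors can be read without loss.

File dialects
-------------
CSV: header ``landmark,x,y``, one point per row, UTF-8, decimal point.
JSON: object with ``subject_id``, ``group`` and ``points`` (name -> [x, y]);
optional ``image_height``.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import (
    DuplicateLandmarkError,
    LandmarkParseError,
    MissingLandmarkError,
    SchemaError,
)

# --------------------------------------------------------------------------
# Vocabulary
# --------------------------------------------------------------------------

HAIRLINE = tuple(f"HL_p{i}" for i in range(1, 10))        # HL_p5 = trichion
EYEBROWS = tuple(f"EB_p{i}" for i in range(1, 7))         # p1-p3 right, p4-p6 left
CONTOUR_P = tuple(f"P{i}" for i in range(1, 14))          # P7 = menton

MIDLINE = ("GLABELLA", "NASION", "PRONASALE", "SUBNASALE", "CUPID_PEAK")

PAIRED = (
    "ALA", "EN", "EX", "IRIS",
    "LIMBUS_MED", "LIMBUS_LAT",
    "LID_UP", "LID_LO",
    "ZY", "CHEILION",
)

CANONICAL_NAMES: frozenset[str] = frozenset(
    HAIRLINE
    + EYEBROWS
    + CONTOUR_P
    + MIDLINE
    + tuple(f"{p}_{s}" for p in PAIRED for s in ("R", "L"))
)

TRICHION = "HL_p5"
MENTON = "P7"

AUX_PREFIX = "AUX_"


def is_valid_name(name: str) -> bool:
    """True for canonical vocabulary names and ``AUX_``-prefixed extras."""
    return name in CANONICAL_NAMES or name.startswith(AUX_PREFIX)


def _mirror_name(name: str) -> str:
    """Name of the landmark that takes this one's place under left-right mirroring."""
    if name.endswith("_R"):
        return name[:-2] + "_L"
    if name.endswith("_L"):
        return name[:-2] + "_R"
    if name.startswith("HL_p"):
        return f"HL_p{10 - int(name[4:])}"
    if name.startswith("EB_p"):
        return f"EB_p{7 - int(name[4:])}"
    if name.startswith("P") and name[1:].isdigit():
        return f"P{14 - int(name[1:])}"
    return name


MIRROR_MAP: dict[str, str] = {n: _mirror_name(n) for n in CANONICAL_NAMES}


class Group(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNSPECIFIED = "unspecified"


# --------------------------------------------------------------------------
# LandmarkSet
# --------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    """Named 2D pixel-space points for one face plus minimal metadata."""

    subject_id: str = ""
    group: Group = Group.UNSPECIFIED
    points: dict[str, tuple[float, float]] = field(default_factory=dict)
    image_height: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.group, str):
            self.group = Group(self.group)
        for name, (x, y) in self.points.items():
            if not is_valid_name(name):
                raise SchemaError(f"unknown landmark name: {name!r}")
            if not (math.isfinite(x) and math.isfinite(y)):
                raise SchemaError(f"non-finite coordinates for {name}: ({x}, {y})")

    def has(self, *names: str) -> bool:
        return all(n in self.points for n in names)

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise MissingLandmarkError(*missing)

    def mirrored(self, axis_x: float = 0.0) -> "LandmarkSet":
        """Left-right mirror image: reflect x about ``axis_x`` and swap side labels."""
        pts = {
            MIRROR_MAP.get(n, n): (2.0 * axis_x - x, y)
            for n, (x, y) in self.points.items()
        }
        return LandmarkSet(self.subject_id, self.group, pts, self.image_height)


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------


def _validated_insert(points: dict, name: str, x: float, y: float, where: str) -> None:
    if not is_valid_name(name):
        raise SchemaError(f"{where}: unknown landmark name {name!r}")
    if name in points:
        raise DuplicateLandmarkError(f"{where}: duplicate landmark {name!r}")
    points[name] = (x, y)


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read one face's landmarks from a ``.csv`` or ``.json`` file."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_json(path)
    return _read_csv(path)


def _read_csv(path: Path) -> LandmarkSet:
    points: dict[str, tuple[float, float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LandmarkParseError(f"{path}: empty file") from None
        if [c.strip().lower() for c in header[:3]] != ["landmark", "x", "y"]:
            raise LandmarkParseError(f"{path}: line 1: expected header 'landmark,x,y'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise LandmarkParseError(f"{path}: line {lineno}: expected 3 fields")
            name = row[0].strip()
            try:
                x, y = float(row[1]), float(row[2])
            except ValueError:
                raise LandmarkParseError(
                    f"{path}: line {lineno}: non-numeric coordinate"
                ) from None
            _validated_insert(points, name, x, y, f"{path}: line {lineno}")
    return LandmarkSet(subject_id=path.stem, points=points)


def _read_json(path: Path) -> LandmarkSet:
    try:
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise LandmarkParseError(f"{path}: invalid JSON: {exc}") from None
    if not isinstance(obj, dict) or "points" not in obj:
        raise LandmarkParseError(f"{path}: expected an object with a 'points' member")
    points: dict[str, tuple[float, float]] = {}
    for name, xy in obj["points"].items():
        if not (isinstance(xy, (list, tuple)) and len(xy) == 2):
            raise LandmarkParseError(f"{path}: point {name!r}: expected [x, y]")
        _validated_insert(points, name, float(xy[0]), float(xy[1]), f"{path}: {name}")
    return LandmarkSet(
        subject_id=str(obj.get("subject_id", path.stem)),
        group=Group(obj.get("group", "unspecified")),
        points=points,
        image_height=obj.get("image_height"),
    )


def write_landmarks(ls: LandmarkSet, path: str | Path) -> None:
    """Write a LandmarkSet; dialect chosen by extension. Coordinates keep 3 decimals."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = {
            "subject_id": ls.subject_id,
            "group": ls.group.value,
            "points": {n: [round(x, 3), round(y, 3)] for n, (x, y) in ls.points.items()},
        }
        if ls.image_height is not None:
            obj["image_height"] = ls.image_height
        path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n", encoding="utf-8")
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["landmark", "x", "y"])
        for name, (x, y) in ls.points.items():
            writer.writerow([name, f"{x:.3f}", f"{y:.3f}"])


def read_cohort(directory: str | Path, group: Group | str | None = None) -> list[LandmarkSet]:
    """Read every ``.csv``/``.json`` landmark file in a directory (sorted by name)."""
    directory = Path(directory)
    out = []
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in (".csv", ".json"):
            ls = read_landmarks(p)
            if group is not None:
                ls.group = Group(group)
            out.append(ls)
    return out
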