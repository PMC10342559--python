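"""Mean facial contours: alignment, pointwise averaging, overlay export.

The facial outline is summarised by 24 landmarks — the nine hairline points,
the two zygoma points and the thirteen lower-face contour points.  Faces are
aligned by translation (subnasale to the origin) and rotation (glabella–
menton midline made vertical) only; size is deliberately *not* normalised,
because absolute size differences between groups are a finding, not
nuisance variation.  The group mean contour is the pointwise arithmetic
mean of the aligned coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calibration import CalibratedFace
from .errors import MissingLandmarkError
from .landmarks_io import Group
from .pose import rotation_matrix_clockwise

#: The 24 contour landmarks, canonical order: hairline, zygomas, jawline.
CONTOUR_POINT_NAMES: tuple[str, ...] = (
    tuple(f"HL_p{i}" for i in range(1, 10))
    + ("ZY_R", "ZY_L")
    + tuple(f"P{i}" for i in range(1, 14))
)

#: Same landmarks ordered for drawing one closed outline
#: (across the hairline, down the viewer-right side, along the jaw, back up).
OUTLINE_ORDER: tuple[str, ...] = (
    tuple(f"HL_p{i}" for i in range(1, 10))
    + ("ZY_L",)
    + tuple(f"P{i}" for i in range(13, 0, -1))
    + ("ZY_R",)
)


@dataclass
class ContourModel:
    group: Group
    point_names: tuple[str, ...]
    mean_points: np.ndarray  # (24, 2) mm, subnasale at the origin
    n_faces: int


def align_face(face: CalibratedFace) -> dict[str, np.ndarray]:
    """Contour points translated to the subnasale and de-rotated (mm, y-up).

    Applies the inverse of the face's in-plane rotation so the glabella→
    menton midline is vertical; absolute millimetre scale is preserved.
    """
    missing = [n for n in CONTOUR_POINT_NAMES + ("SUBNASALE",) if n not in face.points]
    if missing:
        raise MissingLandmarkError(*missing)
    rot = face.rotation_deg
    if rot is None:
        rot = 0.0
    # a clockwise-rotated face is undone by the inverse (counter-clockwise) map
    undo = rotation_matrix_clockwise(-rot)
    origin = face.points["SUBNASALE"]
    return {n: undo @ (face.points[n] - origin) for n in CONTOUR_POINT_NAMES}


def mean_contour(faces, group: Group | str | None = None) -> ContourModel:
    """Pointwise mean of the aligned contours of one group of faces."""
    faces = list(faces)
    if not faces:
        raise ValueError("mean_contour needs at least one face")
    aligned = [align_face(f) for f in faces]
    coords = np.array([[a[n] for n in CONTOUR_POINT_NAMES] for a in aligned])
    if group is None:
        group = faces[0].group
    return ContourModel(
        group=Group(group),
        point_names=CONTOUR_POINT_NAMES,
        mean_points=coords.mean(axis=0),
        n_faces=len(faces),
    )


def export_overlay(a: ContourModel, b: ContourModel, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write an SVG overlay of two mean contours and a paired-coordinates TSV.

    Returns the (svg_path, tsv_path) pair.  The TSV has one row per contour
    landmark with both models' coordinates and their deltas.
    """
    if a.point_names != b.point_names:
        raise ValueError("contour models have different point names")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    svg_path = out_prefix.with_suffix(".svg")
    tsv_path = out_prefix.with_suffix(".tsv")

    idx = {n: i for i, n in enumerate(a.point_names)}
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write(
            f"point\t{a.group.value}_x_mm\t{a.group.value}_y_mm"
            f"\t{b.group.value}_x_mm\t{b.group.value}_y_mm\tdx_mm\tdy_mm\n"
        )
        for n in a.point_names:
            pa, pb = a.mean_points[idx[n]], b.mean_points[idx[n]]
            d = pb - pa
            fh.write(
                f"{n}\t{pa[0]:.3f}\t{pa[1]:.3f}\t{pb[0]:.3f}\t{pb[1]:.3f}"
                f"\t{d[0]:.3f}\t{d[1]:.3f}\n"
            )

    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 6))
    for model, color in ((a, "#4878cf"), (b, "#e377c2")):
        pts = np.array([model.mean_points[idx[n]] for n in OUTLINE_ORDER + OUTLINE_ORDER[:1]])
        ax.plot(pts[:, 0] / 10, pts[:, 1] / 10, "-o", ms=3, color=color,
                label=f"{model.group.value} (n={model.n_faces})")
    ax.plot(0, 0, "o", color="#1f3d99", ms=6)
    ax.annotate("Sn", (0, 0), textcoords="offset points", xytext=(6, -4), fontsize=8)
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm, subnasale origin)")
    ax.set_ylabel("y (cm)")
    ax.legend(loc="lower right", fontsize=8)
    ax.set_title("Mean facial contours")
    fig.tight_layout()
    fig.savefig(svg_path, metadata={"Date": None})
    plt.close(fig)
    return svg_path, tsv_path
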