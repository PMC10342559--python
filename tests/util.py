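"""Shared test helpers: fixture constructors and independent brute-force oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats

from facemorph.calibration import CalibratedFace
from facemorph.landmarks_io import Group, LandmarkSet

#: with a 117.1 px corneal diameter the calibration scale is exactly 0.1 mm/px
DIAMETER_PX = 117.1

LIMBUS_RIGHT = {
    "LIMBUS_MED_R": (500.0, 800.0),
    "LIMBUS_LAT_R": (500.0 - DIAMETER_PX, 800.0),
}


def make_ls(points: dict, group: str = "unspecified", with_limbus: bool = True,
            subject_id: str = "test") -> LandmarkSet:
    """Landmark set from a plain point dict, plus right-eye limbus ruler points."""
    pts = dict(points)
    if with_limbus:
        pts.update(LIMBUS_RIGHT)
    return LandmarkSet(subject_id=subject_id, group=group, points=pts)


def metric_face(points_mm: dict, rotation_deg: float | None = None,
                group: str = "unspecified") -> CalibratedFace:
    """CalibratedFace directly from metric (mm, y-up) points."""
    from facemorph.pose import face_rotation_angle

    pts = {n: np.asarray(p, float) for n, p in points_mm.items()}
    if rotation_deg is None and "GLABELLA" in pts and "P7" in pts:
        rotation_deg = face_rotation_angle(pts["GLABELLA"], pts["P7"])
    return CalibratedFace(subject_id="test", group=Group(group), points=pts,
                          scale_mm_per_px=1.0, rotation_deg=rotation_deg)


def rigid_motion(points: dict, deg: float, shift=(0.0, 0.0)) -> dict:
    """Rotate (math-CCW, metric frame) then translate every point."""
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    rot = np.array([[c, -s], [s, c]])
    return {n: rot @ np.asarray(p, float) + np.asarray(shift, float)
            for n, p in points.items()}


# ---------------------------------------------------------------------------
# Exhaustive-enumeration oracles (independent of scipy)
# ---------------------------------------------------------------------------


def exact_mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney p by enumerating all group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n, m = len(x), len(y)

    def u_stat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in idx]
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)

    observed = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in x for b in y)
    mu = n * m / 2.0
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        total += 1
        if abs(u_stat(set(idx)) - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return count / total


def exact_wilcoxon_p(diff) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments.

    Zero differences are dropped (the usual zero-exclusion rule); ranks of
    tied magnitudes are midranks.
    """
    d = np.asarray([v for v in diff if v != 0], float)
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    count = total = 0
    for signs in itertools.product((0.0, 1.0), repeat=n):
        total += 1
        w = float(np.dot(ranks, signs))
        if abs(w - mu) >= abs(w_plus - mu) - 1e-12:
            count += 1
    return count / total


def brute_force_total_n(d: float, power: float, alpha: float, n_max: int = 400) -> int:
    """Smallest even total n reaching the target power, by scanning the
    noncentral-t power curve directly."""
    for n_per in range(2, n_max):
        df = 2 * n_per - 2
        crit = stats.t.ppf(1 - alpha / 2, df)
        nc = d * math.sqrt(n_per / 2.0)
        achieved = (1 - stats.nct.cdf(crit, df, nc)) + stats.nct.cdf(-crit, df, nc)
        if achieved >= power:
            return 2 * n_per
    raise AssertionError("no n found")
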