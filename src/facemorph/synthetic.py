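"""Synthetic landmark-cohort generator.

Generates pixel-space landmark sets whose measurement distributions match
the gender-specific reference tables, so every pipeline stage can be tested
without photographs.  Per face the generator

1. samples each target measurement independently from its (mean, SD)
   Gaussian, truncated at ±3 SD and floored at small positive lengths;
2. deforms an anatomically ordered template face so that the measurement
   battery on the noiseless output recovers each sampled target (exactly
   for almost all targets; the gonion triple and the lateral brow-to-canthus
   distance are reconciled by a weighted least-squares compromise when the
   independent samples are jointly infeasible — marginal tables of strongly
   correlated quantities occasionally violate the triangle inequality);
3. adds isotropic Gaussian landmark jitter (annotation error, mm);
4. applies a random in-plane head rotation and converts to pixels with a
   sampled white-to-white corneal diameter, emitting limbus points
   consistent with that diameter so each face carries its own calibration.

Because only marginal statistics are published, measurements are sampled
without any covariance model; see docs/methods.md for what this does and
does not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import REFERENCE_CORNEAL_MM
from .errors import GenerationError
from .landmarks_io import Group, LandmarkSet
from .pose import rotation_matrix_clockwise
from .tables import generator_targets

__all__ = ["GeneratorParams", "generate_face", "generate_face_detailed",
           "generate_cohort", "perturb_landmarks"]


@dataclass
class GeneratorParams:
    group: str | Group = "female"
    #: measurement name -> (mean, sd) in cm/degrees; None = group preset tables
    measurement_targets: dict[str, tuple[float, float]] | None = None
    corneal_px_mean: float = 120.0
    corneal_px_sd: float = 12.0
    rotation_sd_deg: float = 3.0
    landmark_jitter_sd_mm: float = 0.3
    #: annotation error of the high-contrast iris boundary; kept well below the
    #: anatomical jitter because limbus error acts multiplicatively on every
    #: measurement through the calibration scale
    limbus_jitter_sd_mm: float = 0.1
    reference_corneal_mm: float = REFERENCE_CORNEAL_MM
    seed: int | None = None
    max_retries: int = 100

    def resolved_targets(self) -> dict[str, tuple[float, float]]:
        if self.measurement_targets is not None:
            return dict(self.measurement_targets)
        return generator_targets(self.group)

    def noiseless(self) -> "GeneratorParams":
        """Copy with all SDs and noise sources zeroed (means-only faces)."""
        targets = {k: (m, 0.0) for k, (m, _) in self.resolved_targets().items()}
        return GeneratorParams(
            group=self.group, measurement_targets=targets,
            corneal_px_mean=self.corneal_px_mean, corneal_px_sd=0.0,
            rotation_sd_deg=0.0, landmark_jitter_sd_mm=0.0, limbus_jitter_sd_mm=0.0,
            reference_corneal_mm=self.reference_corneal_mm, seed=self.seed,
        )


_ANGLE_TARGETS = {"brow_angle_1", "brow_angle_3", "canthal_tilt"}
_MIN_LENGTH_CM = 0.05

# fixed template constants, mm
_CHEILION_X = 25.0
_CUPID_X = 10.0
_EAR_OFFSET = 2.0
_IMG_CX, _IMG_CY, _IMG_H = 1024.0, 1500.0, 3000.0


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0.0:
        return mean
    return mean + sd * float(np.clip(rng.standard_normal(), -3.0, 3.0))


def _sample_targets(params: GeneratorParams, rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for name, (mean, sd) in params.resolved_targets().items():
        v = _trunc_normal(rng, mean, sd)
        if name not in _ANGLE_TARGETS:
            v = max(v, _MIN_LENGTH_CM)
        out[name] = v
    return out


def _feasible(t: dict[str, float]) -> bool:
    g = t["facial_height"] - t["forehead_height"] - t["lower_facial_height"]
    if g < 1.0:
        return False
    cos_tilt = math.cos(math.radians(t["canthal_tilt"]))
    if max(t["palpebral_fissure_width_l"], t["palpebral_fissure_width_r"]) * cos_tilt \
            > t["interpupillary_distance"] - 0.2:
        return False
    return True


def _solve_gonions(m2, m12, bw, sds):
    """Place the two gonions at distances m2/m12 from the subnasale, bw apart.

    All mm.  When the independently sampled triple violates the triangle
    inequality the deficit is redistributed across the three values with
    weights proportional to their table SDs (least-squares compromise on the
    standardised scale); returns the two points and the reconciled triple.
    """
    if bw > m2 + m12:
        w = np.array(sds, float)
        w = w / w.sum()
        deficit = bw - (m2 + m12)
        m2 += w[0] * deficit
        m12 += w[1] * deficit
        bw -= w[2] * deficit
    elif bw < abs(m2 - m12):
        bw = abs(m2 - m12)
    cos_g = (m2 * m2 + m12 * m12 - bw * bw) / (2.0 * m2 * m12)
    half = 0.5 * math.acos(min(1.0, max(-1.0, cos_g)))
    s, c = math.sin(half), math.cos(half)
    p2 = np.array([-m2 * s, -m2 * c])
    p12 = np.array([m12 * s, -m12 * c])
    return p2, p12, (m2, m12, bw)


def _solve_brow_anchor(en, ex, w, mbc, lbc):
    """Medial-brow anchor at distance ``mbc`` from the endocanthion.

    The anchor direction is chosen on the circle of radius ``mbc`` around
    the endocanthion so that the far brow end lands at distance ``lbc`` from
    the exocanthion; of the two solutions the superior one is taken.  If the
    circle and the ``lbc`` sphere do not intersect (rare), the closest point
    is used and the achieved distance is returned.
    """
    q = ex - en - w
    qn = float(np.hypot(*q))
    if qn < 1e-9:
        u = np.array([0.0, 1.0])
    else:
        cos_psi = (mbc * mbc + qn * qn - lbc * lbc) / (2.0 * mbc * qn)
        psi = math.acos(min(1.0, max(-1.0, cos_psi)))
        phi_q = math.atan2(q[1], q[0])
        cands = [phi_q + psi, phi_q - psi]
        u = max((np.array([math.cos(p), math.sin(p)]) for p in cands), key=lambda v: v[1])
    anchor = en + mbc * u
    achieved_lbc = float(np.hypot(*(anchor + w - ex)))
    return anchor, achieved_lbc


def _pinned_contour_point(m, x_pin, x_sign):
    """Contour point at distance ``m`` from the subnasale, below it, with the
    requested |x| where feasible (the distance is always honoured exactly)."""
    x = min(abs(x_pin), 0.999 * m)
    return np.array([x_sign * x, -math.sqrt(m * m - x * x)])


def _build_template(t: dict[str, float], sds: dict[str, float], ref_mm: float):
    """Noiseless metric template (mm, y-up, subnasale at origin) for sampled
    targets ``t`` (cm/degrees).  Returns (points, built) where ``built`` maps
    every battery field to the value the noiseless face measures."""
    mm = {k: 10.0 * v for k, v in t.items() if k not in _ANGLE_TARGETS}
    tau = math.radians(t["canthal_tilt"])
    a1 = math.radians(t["brow_angle_1"])
    a3 = math.radians(t["brow_angle_3"])

    fh, fhh, lfh = mm["facial_height"], mm["forehead_height"], mm["lower_facial_height"]
    g = fh - fhh - lfh                       # glabella height above the subnasale
    y_eye = g - 4.0
    pts: dict[str, np.ndarray] = {
        "SUBNASALE": np.zeros(2),
        "P7": np.array([0.0, -lfh]),
        "GLABELLA": np.array([0.0, g]),
        "HL_p5": np.array([0.0, g + fhh]),
        "PRONASALE": np.array([0.0, 6.0]),
        "NASION": np.array([0.0, 6.0 + mm["nose_length"]]),
        "ALA_R": np.array([-0.5 * mm["alar_width"], 1.0]),
        "ALA_L": np.array([0.5 * mm["alar_width"], 1.0]),
        "ZY_R": np.array([-0.5 * mm["facial_width"], y_eye - 8.0]),
        "ZY_L": np.array([0.5 * mm["facial_width"], y_eye - 8.0]),
        "HL_p1": np.array([-0.5 * mm["forehead_width"], g]),
        "HL_p9": np.array([0.5 * mm["forehead_width"], g]),
    }

    # eyes: iris centred between the canthi, canthal line tilted by tau
    ipd = mm["interpupillary_distance"]
    pts["IRIS_R"] = np.array([-0.5 * ipd, y_eye])
    pts["IRIS_L"] = np.array([0.5 * ipd, y_eye])
    ct, st = math.cos(tau), math.sin(tau)
    for side, lat_sign in (("R", -1.0), ("L", 1.0)):
        iris = pts[f"IRIS_{side}"]
        pfw = mm[f"palpebral_fissure_width_{side.lower()}"]
        pfh = mm[f"palpebral_fissure_height_{side.lower()}"]
        lat = np.array([lat_sign * ct, st])          # medial -> lateral, tilted up
        pts[f"EN_{side}"] = iris - 0.5 * pfw * lat
        pts[f"EX_{side}"] = iris + 0.5 * pfw * lat
        pts[f"LID_UP_{side}"] = iris + np.array([0.0, 0.5 * pfh])
        pts[f"LID_LO_{side}"] = iris - np.array([0.0, 0.5 * pfh])
        pts[f"LIMBUS_MED_{side}"] = iris + np.array([-lat_sign * 0.5 * ref_mm, 0.0])
        pts[f"LIMBUS_LAT_{side}"] = iris + np.array([lat_sign * 0.5 * ref_mm, 0.0])

    # eyebrows: lengths and angles fixed, anchored to match both
    # brow-to-canthus distances where jointly feasible
    mbc = mm["med_brow_to_med_canthus_avg"]
    lbc = mm["lat_brow_to_lat_canthus_avg"]
    lbc_achieved = []
    for side, lat_sign in (("R", -1.0), ("L", 1.0)):
        ml = mm[f"medial_brow_len_{side.lower()}"]
        ll = mm[f"lateral_brow_len_{side.lower()}"]
        d_med = np.array([lat_sign * math.cos(a1), math.sin(a1)]) * ml
        d_lat = np.array([lat_sign * math.cos(a3), -math.sin(a3)]) * ll
        anchor, got = _solve_brow_anchor(
            pts[f"EN_{side}"], pts[f"EX_{side}"], d_med + d_lat, mbc, lbc
        )
        lbc_achieved.append(got)
        if side == "R":
            pts["EB_p3"], pts["EB_p2"] = anchor, anchor + d_med
            pts["EB_p1"] = anchor + d_med + d_lat
        else:
            pts["EB_p4"], pts["EB_p5"] = anchor, anchor + d_med
            pts["EB_p6"] = anchor + d_med + d_lat

    # hairline: points vertically above their eyebrow counterparts
    for hl, eb, key in (("HL_p2", "EB_p1", "fh_m1"), ("HL_p3", "EB_p2", "fh_m2"),
                        ("HL_p4", "EB_p3", "fh_m3"), ("HL_p6", "EB_p4", "fh_m5"),
                        ("HL_p7", "EB_p5", "fh_m6"), ("HL_p8", "EB_p6", "fh_m7")):
        pts[hl] = pts[eb] + np.array([0.0, mm[key]])

    # mouth
    y_mouth = -0.33 * lfh
    pts["CHEILION_R"] = np.array([-_CHEILION_X, y_mouth])
    pts["CHEILION_L"] = np.array([_CHEILION_X, y_mouth])
    pts["CUPID_PEAK"] = np.array([0.0, y_mouth + 4.0])

    # lower facial contour: gonion triple solved jointly, the rest pinned to
    # anatomical vertical lines with the subnasale distance honoured exactly
    p2, p12, (m2_b, m12_b, bw_b) = _solve_gonions(
        mm["m2"], mm["m12"], mm["bigonial_width"],
        (sds["m2"], sds["m12"], sds["bigonial_width"]),
    )
    pts["P2"], pts["P12"] = p2, p12
    pins = {
        1: abs(p2[0]) + _EAR_OFFSET, 13: abs(p12[0]) + _EAR_OFFSET,
        3: abs(pts["EX_R"][0]), 11: abs(pts["EX_L"][0]),
        4: _CHEILION_X, 10: _CHEILION_X,
        5: abs(pts["EN_R"][0]), 9: abs(pts["EN_L"][0]),
        6: _CUPID_X, 8: _CUPID_X,
    }
    for k, pin in pins.items():
        pts[f"P{k}"] = _pinned_contour_point(mm[f"m{k}"], pin, -1.0 if k < 7 else 1.0)

    # what the battery will measure on this noiseless face, cm/degrees
    built = dict(t)
    built.update({
        "mid_facial_height": g / 10.0,
        "fh_m4": t["forehead_height"],
        "m7": t["lower_facial_height"],
        "m2": m2_b / 10.0, "m12": m12_b / 10.0, "bigonial_width": bw_b / 10.0,
        "lat_brow_to_lat_canthus_avg": 0.5 * sum(lbc_achieved) / 10.0,
        "brow_angle_2": t["brow_angle_1"] + t["brow_angle_3"],
    })
    for side in ("l", "r"):
        built[f"total_brow_len_{side}"] = (
            built[f"medial_brow_len_{side}"] + built[f"lateral_brow_len_{side}"]
        )
    for a, b_, avg in (("fh_m1", "fh_m7", "avg_fh_m1_m7"),
                       ("fh_m2", "fh_m6", "avg_fh_m2_m6"),
                       ("fh_m3", "fh_m5", "avg_fh_m3_m5")):
        built[avg] = 0.5 * (built[a] + built[b_])
    for stem in ("palpebral_fissure_height", "palpebral_fissure_width",
                 "medial_brow_len", "lateral_brow_len", "total_brow_len"):
        built[f"{stem}_avg"] = 0.5 * (built[f"{stem}_l"] + built[f"{stem}_r"])
    for k in range(1, 7):
        built[f"avg_m{k}_m{14 - k}"] = 0.5 * (built[f"m{k}"] + built[f"m{14 - k}"])
    return pts, built


def generate_face_detailed(
    params: GeneratorParams,
    rng: np.random.Generator,
    subject_id: str = "synthetic",
) -> tuple[LandmarkSet, dict[str, float]]:
    """One face plus the measurement values it was built to have.

    The second element maps every battery field to the value the noiseless
    template realises (sampled targets after any feasibility reconciliation,
    plus derived averages), which the measurement battery recovers exactly
    up to jitter.
    """
    sds = {k: sd for k, (_, sd) in params.resolved_targets().items()}
    for _ in range(params.max_retries):
        t = _sample_targets(params, rng)
        if _feasible(t):
            break
    else:
        raise GenerationError(
            f"no feasible target combination in {params.max_retries} attempts"
        )
    pts, built = _build_template(t, sds, params.reference_corneal_mm)

    rho = _trunc_normal(rng, 0.0, params.rotation_sd_deg)
    corneal_px = max(_trunc_normal(rng, params.corneal_px_mean, params.corneal_px_sd), 10.0)
    rot = rotation_matrix_clockwise(rho)
    names = list(pts)
    sd_per_point = np.array([
        params.limbus_jitter_sd_mm if n.startswith("LIMBUS_") else params.landmark_jitter_sd_mm
        for n in names
    ])
    if np.any(sd_per_point > 0):
        noise = rng.normal(0.0, 1.0, size=(len(names), 2)) * sd_per_point[:, None]
    else:
        noise = np.zeros((len(names), 2))
    px_per_mm = corneal_px / params.reference_corneal_mm
    pixel_points: dict[str, tuple[float, float]] = {}
    for name, eps in zip(names, noise):
        x, y = rot @ pts[name] + eps
        pixel_points[name] = (_IMG_CX + x * px_per_mm, _IMG_CY - y * px_per_mm)
    built["face_rotation_deg"] = rho
    ls = LandmarkSet(
        subject_id=subject_id,
        group=Group(getattr(params.group, "value", params.group)),
        points=pixel_points,
        image_height=_IMG_H,
    )
    return ls, built


def generate_face(params: GeneratorParams, rng: np.random.Generator,
                  subject_id: str = "synthetic") -> LandmarkSet:
    return generate_face_detailed(params, rng, subject_id)[0]


def generate_cohort(params: GeneratorParams, n: int,
                    seed: int | None = None) -> list[LandmarkSet]:
    """n independent faces from one seeded stream, with unique subject ids."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    group = getattr(params.group, "value", params.group)
    return [
        generate_face(params, rng, subject_id=f"{group}_{i + 1:03d}")
        for i in range(n)
    ]


def perturb_landmarks(ls: LandmarkSet, sd_px: float, rng: np.random.Generator,
                      limbus_sd_px: float | None = None) -> LandmarkSet:
    """Isotropic Gaussian pixel jitter on every landmark (annotation error).

    The limbus calibration points get their own (usually smaller) error,
    mirroring the generator's noise model; by default one third of ``sd_px``.
    """
    if limbus_sd_px is None:
        limbus_sd_px = sd_px / 3.0
    names = list(ls.points)
    sd = np.array([limbus_sd_px if n.startswith("LIMBUS_") else sd_px for n in names])
    noise = rng.normal(0.0, 1.0, size=(len(names), 2)) * sd[:, None]
    pts = {n: (x + e[0], y + e[1]) for (n, (x, y)), e in zip(ls.points.items(), noise)}
    return LandmarkSet(ls.subject_id, ls.group, pts, ls.image_height)
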