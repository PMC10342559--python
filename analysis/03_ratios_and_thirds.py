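#!/usr/bin/env python
"""Facial proportions R1-R10 and horizontal/vertical thirds per cohort.

Reads the landmark cohorts, computes per-subject proportions (mean of
ratios) and prints the group means with the golden-ratio comparison for
facial height : bigonial width (R5).
"""

import argparse
from pathlib import Path

from facemorph.calibration import calibrate_face
from facemorph.landmarks_io import read_cohort
from facemorph.measurements import measure_face
from facemorph.pipeline import ratio_frame
from facemorph.ratios import GOLDEN_RATIO, format_triple


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    for group in ("female", "male"):
        cohort = read_cohort(args.results / "landmarks" / group, group=group)
        records = [measure_face(ls) for ls in cohort]
        faces = [calibrate_face(ls) for ls in cohort]
        frame = ratio_frame(records, faces)
        out = args.results / f"ratios_{group}.tsv"
        frame.to_csv(out, sep="\t", index=False, float_format="%.4f")
        r5 = frame["r1"].mean(), frame["r5"].mean()
        h = (1.0, frame["thirds_h_mid"].mean(), frame["thirds_h_lower"].mean())
        v = (frame["thirds_v_right"].mean(), frame["thirds_v_mid"].mean(),
             frame["thirds_v_left"].mean())
        print(f"{group}: R1 {r5[0]:.2f}; R5 {r5[1]:.2f} "
              f"(golden ratio {GOLDEN_RATIO}, gap {abs(r5[1] - GOLDEN_RATIO):.3f})")
        print(f"  horizontal thirds {format_triple(h)}; vertical thirds {format_triple(v)}"
              f" -> {out}")


if __name__ == "__main__":
    main()
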