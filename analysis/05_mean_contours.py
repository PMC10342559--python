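#!/usr/bin/env python
"""Mean male and female facial contours, aligned and overlaid.

Aligns every face by subnasale translation and midline de-rotation (no size
normalisation — absolute size differences are a finding), averages the 24
contour landmarks per group, and writes contours.svg / contours.tsv.
"""

import argparse
from pathlib import Path

from facemorph.calibration import calibrate_face
from facemorph.contour import export_overlay, mean_contour
from facemorph.landmarks_io import read_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    models = {}
    for group in ("female", "male"):
        cohort = read_cohort(args.results / "landmarks" / group, group=group)
        models[group] = mean_contour([calibrate_face(ls) for ls in cohort], group)

    svg, tsv = export_overlay(models["male"], models["female"],
                              args.results / "contours")
    idx = dict(zip(models["male"].point_names, range(24)))
    gap = (models["female"].mean_points[idx["P7"]][1]
           - models["male"].mean_points[idx["P7"]][1])
    print(f"wrote {svg} and {tsv}")
    print(f"menton sits {gap / 10:.2f} cm lower in the male mean contour")


if __name__ == "__main__":
    main()
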