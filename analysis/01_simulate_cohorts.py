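#!/usr/bin/env python
"""Generate the 21 + 21 synthetic landmark cohorts at the reference presets.

Writes one CSV landmark file per face under results/landmarks/{female,male}/.
Every downstream step (02-05) starts from these files, mirroring a workflow
whose input is a directory of per-photo landmark annotations.
"""

import argparse
from pathlib import Path

from facemorph.landmarks_io import write_landmarks
from facemorph.synthetic import GeneratorParams, generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--n", type=int, default=21)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    for offset, group in ((0, "female"), (1, "male")):
        out = args.results / "landmarks" / group
        out.mkdir(parents=True, exist_ok=True)
        cohort = generate_cohort(GeneratorParams(group=group), args.n,
                                 seed=args.seed + offset)
        for ls in cohort:
            write_landmarks(ls, out / f"{ls.subject_id}.csv")
        print(f"{group}: wrote {len(cohort)} landmark files to {out}")


if __name__ == "__main__":
    main()
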