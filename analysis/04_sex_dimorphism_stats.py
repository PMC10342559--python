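#!/usr/bin/env python
"""Female-vs-male statistics over the full battery, in the nine-table layout.

Runs Welch t-tests (Mann-Whitney selectable) per measurement and writes the
familiar summary tables; prints the significantly dimorphic measurements.
"""

import argparse
from pathlib import Path

from facemorph.landmarks_io import read_cohort
from facemorph.measurements import measure_face, records_to_frame
from facemorph.cohort_stats import summarize
from facemorph.pipeline import _TABLE_BLOCKS


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--test", choices=["welch_t", "mann_whitney"], default="welch_t")
    args = ap.parse_args()

    frames = {}
    for group in ("female", "male"):
        cohort = read_cohort(args.results / "landmarks" / group, group=group)
        frames[group] = records_to_frame([measure_face(ls) for ls in cohort])

    for name, fields in _TABLE_BLOCKS.items():
        table = summarize(frames["female"], frames["male"], test=args.test,
                          fields=list(fields), group_names=("female", "male"))
        out = args.results / f"{name}.tsv"
        table.to_csv(out, sep="\t", index=False, float_format="%.4f")
        hits = table[table["p_value"] < 0.05]["measurement"].tolist()
        print(f"{name}: {len(table)} measurements, p<0.05 for {hits or 'none'}")


if __name__ == "__main__":
    main()
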