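#!/usr/bin/env python
"""Compute the four per-patient desaturation measures from the oximetry
streams: median-of-sliding-medians, minutes/hour below the threshold
level, nadir SpO2 (manual room-air entries included), and oxygen-therapy
exposure.  Central tendency and duration are censored at 120 minutes;
nadir and oxygen use the full stay.
"""

import argparse
from pathlib import Path

from pacudesat import synthetic
from pacudesat.oximetry import measures_table
from pacudesat.pipeline import read_oximetry_csv, write_csv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--level", type=float, default=94.0,
                    help="desaturation level for the duration measure (%% SpO2)")
    ap.add_argument("--out", type=Path, default=Path("results/measures.csv"))
    args = ap.parse_args()

    frame = read_oximetry_csv(args.cohort_dir / "oximetry.csv")
    streams = synthetic.frame_to_streams(frame)
    measures = measures_table(streams, level=args.level)
    write_csv(measures, args.out)

    desc = measures[["median_spo2", "nadir_spo2", "minutes_below_level_per_hour", "o2_fraction"]].describe()
    print(f"measures for {len(measures)} patients -> {args.out}")
    print(desc.loc[["mean", "50%", "min", "max"]].round(2).to_string())
    miss = measures.isna().mean() * 100
    print("missing %:", miss[miss > 0].round(1).to_dict() or "none")


if __name__ == "__main__":
    main()
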