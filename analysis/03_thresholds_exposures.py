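#!/usr/bin/env python
"""Derive population-centile thresholds and assign modeling exposures.

10th centile of per-patient medians and nadirs, 90th centile of
desaturation duration, oxygen-fraction quartiles, and 75th-centile flags
for the dose/duration/complexity covariates.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from pacudesat import phenotyping
from pacudesat.pipeline import _augment_patient_table, write_csv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--measures", type=Path, default=Path("results/measures.csv"))
    ap.add_argument("--patients", type=Path, default=Path("results/cohort/patients.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    measures = pd.read_csv(args.measures)
    patients = _augment_patient_table(pd.read_csv(args.patients))
    thresholds = phenotyping.derive_thresholds(measures, patients)
    exposures = phenotyping.assign_exposures(measures, thresholds, patients)

    (args.out_dir / "thresholds.json").write_text(json.dumps(thresholds.as_dict(), indent=1))
    write_csv(exposures, args.out_dir / "exposures.csv")

    print("derived thresholds:")
    for k, v in thresholds.as_dict().items():
        if k != "n_used" and v is not None:
            print(f"  {k}: {v}")
    for col in ("nadir_low", "median_low", "duration_high"):
        print(f"{col}: {100 * exposures[col].mean():.1f}% of patients")
    print(f"wrote {args.out_dir}/thresholds.json and exposures.csv")


if __name__ == "__main__":
    main()
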