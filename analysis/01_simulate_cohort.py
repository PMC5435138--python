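#!/usr/bin/env python
"""Generate the synthetic PACU cohort used by the downstream analyses.

Writes the long-format oximetry table, the one-row-per-patient covariate /
outcome / charge table, and the latent generating truth (kept separate —
no analysis stage may read it) under results/cohort/.
"""

import argparse
from pathlib import Path

from pacudesat.config import SimulationConfig
from pacudesat import synthetic
from pacudesat.pipeline import write_csv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=20_000)
    ap.add_argument("--out-dir", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    cfg = SimulationConfig(n_patients=args.n, seed=args.seed)
    streams, patients, truth = synthetic.generate_cohort(cfg)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    write_csv(synthetic.streams_to_frame(streams), args.out_dir / "oximetry.csv")
    write_csv(patients, args.out_dir / "patients.csv")
    (args.out_dir / "truth.json").write_text(truth.to_json())

    inc = patients["early_prc"].mean()
    print(f"simulated {len(patients)} patients, seed {args.seed}")
    print(f"early-PRC incidence: {100 * inc:.2f}% ({patients['early_prc'].sum()} events)")
    print(f"wrote {args.out_dir}/oximetry.csv, patients.csv, truth.json")


if __name__ == "__main__":
    main()
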