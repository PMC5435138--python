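#!/usr/bin/env python
"""Propensity-matched resource-utilization comparison.

Exposure: oxygen-therapy duration above the lowest quartile.  Rare
procedure categories (fewer than 50 patients) are excluded; a logistic
propensity model on pre/intra-operative covariates plus body-region
indicators yields scores for greedy 1:1 nearest-neighbor matching without
replacement.  Balance (SMDs, tests) and matched secondary outcomes
(charges, length of stay, reintubation, ventilatory support) are written
under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from pacudesat import matching as m
from pacudesat.pipeline import write_csv

COVARS = ["copd", "renal_disease", "chf", "neuro_disease", "steroid", "pneumonia",
          "sepsis", "smoking", "asa_4_5", "high_risk_surgery"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--patients", type=Path, default=Path("results/cohort/patients.csv"))
    ap.add_argument("--exposures", type=Path, default=Path("results/exposures.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--floor", type=int, default=50)
    args = ap.parse_args()

    merged = pd.read_csv(args.patients).merge(pd.read_csv(args.exposures), on="patient_id")
    recs = merged.set_index("patient_id")
    recs["o2_long"] = (recs["o2_quartile"] > 1).astype(float)

    kept, excl = m.exclude_rare_procedures(recs, floor=args.floor)
    if len(excl):
        print("excluded rare procedures:", excl.to_dict("records"))
    scores = m.fit_propensity(kept, "o2_long", COVARS)
    matched = m.nearest_neighbor_match(scores, kept["o2_long"])
    print(f"matched {matched.n_pairs} pairs; {len(matched.unmatched_exposed)} exposed unmatched")

    balance = m.balance_table(matched, kept, COVARS, "o2_long")
    write_csv(balance, args.out_dir / "balance.csv")
    print(balance[["variable", "pre_smd", "post_smd", "post_p"]].round(3).to_string(index=False))

    outcomes = m.matched_outcomes(
        matched, kept,
        ["total_charges", "day_of_surgery_charges", "respiratory_charges", "hospital_los_days"],
        ["reintubation", "vent_support"],
    )
    write_csv(matched.pairs, args.out_dir / "matched_pairs.csv")
    write_csv(outcomes, args.out_dir / "matched_outcomes.csv")
    print(outcomes.round(3).to_string(index=False))

    write_csv(m.charges_by_o2_quartile(kept), args.out_dir / "charges_by_quartile_unmatched.csv")
    matched_recs = kept.loc[pd.concat([matched.pairs["exposed_id"], matched.pairs["control_id"]])]
    write_csv(m.charges_by_o2_quartile(matched_recs), args.out_dir / "charges_by_quartile_matched.csv")
    print(f"wrote pairs/balance/outcomes/charge tables to {args.out_dir}")


if __name__ == "__main__":
    main()
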