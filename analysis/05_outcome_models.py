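#!/usr/bin/env python
"""Adjusted models of early PRC on the synthetic cohort.

Change-in-estimate backward selection anchored on the nadir-desaturation
exposure, the exposure-by-surgical-risk interaction decision, stratified
models when the interaction is significant, and the diagnostics battery
(c-statistic, Hosmer-Lemeshow, VIF, condition indices, omnibus test).
"""

import argparse
from pathlib import Path

import pandas as pd

from pacudesat import modeling
from pacudesat.pipeline import write_csv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--patients", type=Path, default=Path("results/cohort/patients.csv"))
    ap.add_argument("--exposures", type=Path, default=Path("results/exposures.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    merged = pd.read_csv(args.patients).merge(pd.read_csv(args.exposures), on="patient_id")
    covars = ["copd", "renal_disease", "chf", "neuro_disease", "steroid", "pneumonia",
              "sepsis", "smoking", "asa_4_5"]
    candidates = modeling.viable_candidates(merged, "early_prc", covars)
    spec = modeling.ModelSpec("early_prc", ["nadir_low"], candidates)

    model = modeling.change_in_estimate_selection(spec, merged)
    write_csv(model.summary_frame(), args.out_dir / "model_primary.csv")
    write_csv(pd.DataFrame(model.dropped_terms), args.out_dir / "model_ledger.csv")

    print(f"candidates screened: {candidates}")
    print(model.summary_frame().round(3).to_string(index=False))
    d = model.diagnostics
    if d is not None:
        print(f"c-statistic {d.c_statistic:.3f} (SE {d.c_se:.3f}); "
              f"HL chi2 {d.hosmer_lemeshow:.2f} on {d.hl_df} df (p {d.hl_p:.3f}); "
              f"max VIF {max(d.vif.values()):.2f}; max condition index "
              f"{max(d.condition_indices):.1f}; omnibus chi2 {d.omnibus_chi2:.1f} "
              f"on {d.omnibus_df} df")

    inter = modeling.interaction_analysis(merged, "early_prc", "nadir_low", "high_risk_surgery")
    print(f"\ninteraction (nadir_low x high_risk_surgery): product-term p = {inter.product_p:.3f}; "
          f"stratify = {inter.stratify}")
    if inter.stratify:
        strata = modeling.stratified_models(spec, merged, "high_risk_surgery")
        for level, fit in strata.items():
            if isinstance(fit, modeling.FittedModel):
                print(f"stratum {level}: nadir AOR {fit.aor['nadir_low']:.2f}")
                write_csv(fit.summary_frame(), args.out_dir / f"model_stratum_{level}.csv")
            else:
                print(f"stratum {level}: failed ({fit})")


if __name__ == "__main__":
    main()
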