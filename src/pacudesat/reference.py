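"""Published reference counts from a large academic-center PACU cohort.

A previously published single-center cohort (N = 125,740 adult surgical
patients, 351 early respiratory complications) reports the frequency
distribution of risk factors across outcome groups.  The printed counts
for rows without missingness are embedded here as an arithmetic fixture:
recomputing their unadjusted odds ratios and Woolf intervals from raw
counts exercises the univariate machinery against independently printed
values.

Each entry gives (a, c) = (outcome-positive exposed, outcome-negative
exposed); the unexposed cells follow from the column totals.
"""

from __future__ import annotations

from typing import Dict, Tuple

import pandas as pd

from .univariate import TwoByTwo, odds_ratio_woolf

TOTAL_N = 125_740
N_PRC = 351
N_NO_PRC = 125_389

#: variable -> (PRC & exposed, no-PRC & exposed)
EXPOSED_COUNTS: Dict[str, Tuple[int, int]] = {
    "copd": (52, 6_979),
    "renal_disease": (70, 10_670),
    "naloxone": (19, 747),
    "pca": (5, 170),
    "sepsis": (9, 959),
    "high_dose_rocuronium": (13, 1_278),
}

#: published 1-decimal odds ratios and 95% CIs for the same rows
PUBLISHED_OR: Dict[str, Tuple[float, float, float]] = {
    "copd": (3.0, 2.2, 4.0),
    "renal_disease": (2.7, 2.1, 3.5),
    "naloxone": (9.5, 6.0, 15.2),
    "pca": (10.6, 4.3, 26.1),
    "sepsis": (3.4, 1.8, 6.6),
    "high_dose_rocuronium": (3.7, 2.1, 6.5),
}

#: desaturation-phenotype prevalence counts over the full cohort
PHENOTYPE_COUNTS: Dict[str, int] = {
    "nadir_low": 111 + 17_895,
    "median_low": 61 + 18_207,
    "duration_high": 73 + 13_335,
}


def reference_table(alpha: float = 0.05) -> pd.DataFrame:
    """Recompute ORs/CIs for the reference rows from the raw counts."""
    rows = []
    for var, (a, c) in EXPOSED_COUNTS.items():
        t = TwoByTwo(a=a, b=N_PRC - a, c=c, d=N_NO_PRC - c)
        or_, lo, hi, _ = odds_ratio_woolf(t, alpha=alpha)
        rows.append({"variable": var, "odds_ratio": or_, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def cohort_fractions() -> Dict[str, float]:
    """Cohort-level percentages: outcome incidence and phenotype prevalences."""
    out = {"early_prc_pct": 100.0 * N_PRC / TOTAL_N}
    for name, count in PHENOTYPE_COUNTS.items():
        out[f"{name}_pct"] = 100.0 * count / TOTAL_N
    return out
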