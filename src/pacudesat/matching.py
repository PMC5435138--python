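"""Propensity-score matching and matched secondary-outcome comparison.

The exposure is prolonged PACU oxygen therapy (duration above the lowest
quartile).  A logistic propensity model on pre/intra-operative covariates
yields per-patient scores; matching is greedy 1:1 nearest neighbor without
replacement, walking exposed patients in descending score order, each
taking the unused control with the smallest score distance (ties to the
lowest control index).  Balance is verified with standardized mean
differences and the univariate module's tests; outcomes (charges, length
of stay, reintubation, ventilatory support) are compared on the matched
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .modeling import ModelSpec, fit_logistic, _design
from .univariate import TwoByTwo, chi_square_test, continuous_comparison, odds_ratio_woolf


@dataclass
class MatchedCohort:
    pairs: pd.DataFrame                 # exposed_id, control_id, abs_delta
    unmatched_exposed: List[str] = field(default_factory=list)
    discarded_by_caliper: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def exclude_rare_procedures(
    records: pd.DataFrame, floor: int = 50, procedure_col: str = "procedure_region"
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop procedure categories with fewer than ``floor`` patients.

    Returns (filtered records, exclusion log of category/count).  Rejects
    when nothing survives.
    """
    counts = records[procedure_col].value_counts()
    excluded = counts[counts < floor]
    log = excluded.rename_axis("category").reset_index(name="count")
    kept = records[~records[procedure_col].isin(excluded.index)].copy()
    if kept.empty:
        raise ValueError(f"procedure floor {floor} excluded every record")
    return kept, log


def fit_propensity(
    records: pd.DataFrame,
    exposure_col: str,
    covariates: Sequence[str],
    procedure_col: Optional[str] = "procedure_region",
) -> pd.Series:
    """Fitted exposure probabilities from a logistic propensity model.

    Body-region indicators for the procedure column are added to the
    stated covariates.  Only pre/intra-operative variables belong here —
    post-PACU variables would control for consequences of the exposure.
    """
    work = records.copy()
    cols = list(covariates)
    if procedure_col is not None and procedure_col in work:
        dummies = pd.get_dummies(work[procedure_col].astype(str), prefix="region", drop_first=True)
        work = pd.concat([work, dummies.astype(float)], axis=1)
        cols += list(dummies.columns)
    spec = ModelSpec(exposure_col, cols)
    model = fit_logistic(spec, work)
    X = _design(work[[exposure_col] + cols].dropna(), cols)
    lp = X @ pd.Series(model.params)[X.columns]
    return pd.Series(1.0 / (1.0 + np.exp(-lp)), index=X.index, name="propensity")


def nearest_neighbor_match(
    scores: pd.Series,
    exposed: pd.Series,
    caliper: Optional[float] = None,
    order: str = "descending",
    seed: Optional[int] = None,
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Exposed patients are processed in descending propensity order (or a
    seeded random order when ``order='random'``); each takes the unused
    control with the minimal |score difference|, ties broken toward the
    lowest control index.  With a caliper, pairs wider than it are
    discarded and the exposed patient reported unmatched.
    """
    scores = scores.astype(float)
    exposed = exposed.astype(bool).reindex(scores.index)
    exp_ids = list(scores.index[exposed])
    ctl_ids = list(scores.index[~exposed])
    if not exp_ids or not ctl_ids:
        raise ValueError("both exposure groups must be non-empty")

    if order == "descending":
        exp_ids.sort(key=lambda i: -scores[i])
    elif order == "random":
        rng = np.random.default_rng(seed)
        rng.shuffle(exp_ids)
    else:
        raise ValueError(f"unknown order {order!r}")

    # controls sorted by (score, original index rank) for nearest lookup
    ctl_rank = {cid: k for k, cid in enumerate(ctl_ids)}
    ctl_sorted = sorted(ctl_ids, key=lambda i: (scores[i], ctl_rank[i]))
    ctl_scores = np.array([scores[i] for i in ctl_sorted])
    used = np.zeros(len(ctl_sorted), dtype=bool)

    pairs, unmatched = [], []
    discarded = 0
    for eid in exp_ids:
        s = scores[eid]
        pos = int(np.searchsorted(ctl_scores, s))
        best = None
        # scan outward for the nearest unused control; among equal |delta|
        # prefer the lowest original control index
        lo, hi = pos - 1, pos
        candidates = []
        while lo >= 0 and used[lo]:
            lo -= 1
        while hi < len(ctl_sorted) and used[hi]:
            hi += 1
        if lo >= 0:
            candidates.append(lo)
        if hi < len(ctl_sorted):
            candidates.append(hi)
        # equal-|delta| ties sit at scores s-dbest and s+dbest, which are
        # contiguous runs in the sorted array: collect unused controls there
        # and take the lowest original index
        if candidates:
            dbest = min(abs(ctl_scores[c] - s) for c in candidates)
            tied = set()
            for c in candidates:
                if abs(ctl_scores[c] - s) != dbest:
                    continue
                # every unused control sharing this score is at the same
                # distance; scores are sorted so they form a contiguous run
                left = int(np.searchsorted(ctl_scores, ctl_scores[c], side="left"))
                right = int(np.searchsorted(ctl_scores, ctl_scores[c], side="right"))
                tied.update(k for k in range(left, right) if not used[k])
            best = min(tied, key=lambda c: ctl_rank[ctl_sorted[c]])
        if best is None:
            unmatched.append(eid)
            continue
        delta = abs(ctl_scores[best] - s)
        if caliper is not None and delta > caliper:
            discarded += 1
            unmatched.append(eid)
            continue
        used[best] = True
        pairs.append({"exposed_id": eid, "control_id": ctl_sorted[best], "abs_delta": float(delta)})

    return MatchedCohort(
        pairs=pd.DataFrame(pairs, columns=["exposed_id", "control_id", "abs_delta"]),
        unmatched_exposed=unmatched,
        discarded_by_caliper=discarded,
    )


def standardized_mean_difference(x1: np.ndarray, x0: np.ndarray, binary: bool) -> float:
    """Difference of means over the pooled SD (pooled binary SD for 0/1
    variables); 0 by convention when both groups are constant."""
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    m1, m0 = np.nanmean(x1), np.nanmean(x0)
    if binary:
        pooled = np.sqrt((m1 * (1 - m1) + m0 * (1 - m0)) / 2.0)
    else:
        pooled = np.sqrt((np.nanvar(x1, ddof=1) + np.nanvar(x0, ddof=1)) / 2.0)
    if pooled == 0 or np.isnan(pooled):
        return 0.0
    return float((m1 - m0) / pooled)


def _is_binary(series: pd.Series) -> bool:
    vals = set(series.dropna().unique())
    return vals <= {0, 1, 0.0, 1.0, True, False}


def balance_table(
    matched: MatchedCohort,
    records: pd.DataFrame,
    variables: Sequence[str],
    exposure_col: str,
) -> pd.DataFrame:
    """Pre/post-match balance: group stats, p-values, and SMDs per variable."""
    recs = records
    pre1 = recs[recs[exposure_col] == 1]
    pre0 = recs[recs[exposure_col] == 0]
    post1 = recs.loc[matched.pairs["exposed_id"]]
    post0 = recs.loc[matched.pairs["control_id"]]
    rows = []
    for var in variables:
        binary = _is_binary(recs[var])
        row: Dict[str, object] = {"variable": var, "binary": binary}
        for tag, g1, g0 in [("pre", pre1, pre0), ("post", post1, post0)]:
            a1, a0 = g1[var].to_numpy(dtype=float), g0[var].to_numpy(dtype=float)
            if len(a1) == 0 or len(a0) == 0:
                row.update(
                    {
                        f"{tag}_mean_exposed": np.nan,
                        f"{tag}_mean_control": np.nan,
                        f"{tag}_smd": np.nan,
                        f"{tag}_p": np.nan,
                    }
                )
                continue
            row[f"{tag}_mean_exposed"] = float(np.nanmean(a1))
            row[f"{tag}_mean_control"] = float(np.nanmean(a0))
            row[f"{tag}_smd"] = standardized_mean_difference(a1, a0, binary)
            try:
                if binary:
                    tab = np.array(
                        [
                            [np.nansum(a1 == 1), np.nansum(a0 == 1)],
                            [np.nansum(a1 == 0), np.nansum(a0 == 0)],
                        ]
                    )
                    _, _, p = chi_square_test(tab)
                else:
                    p = continuous_comparison([a1, a0], method="mann_whitney")["p"]
            except (ValueError, Warning):
                p = np.nan
            row[f"{tag}_p"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def matched_outcomes(
    matched: MatchedCohort,
    records: pd.DataFrame,
    continuous_outcomes: Sequence[str],
    binary_outcomes: Sequence[str],
) -> pd.DataFrame:
    """Secondary-outcome comparison on the matched pairs.

    Continuous outcomes as median [IQR] with Mann-Whitney p; binary
    outcomes as counts with the Woolf 2x2 OR and chi-square p.
    """
    g1 = records.loc[matched.pairs["exposed_id"]]
    g0 = records.loc[matched.pairs["control_id"]]
    rows = []
    for var in continuous_outcomes:
        res = continuous_comparison([g1[var].to_numpy(), g0[var].to_numpy()], method="mann_whitney")
        s1, s0 = res["groups"]
        rows.append(
            {
                "outcome": var, "type": "continuous",
                "exposed_median": s1["median"], "exposed_q25": s1["q25"], "exposed_q75": s1["q75"],
                "control_median": s0["median"], "control_q25": s0["q25"], "control_q75": s0["q75"],
                "p_value": res["p"], "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            }
        )
    for var in binary_outcomes:
        a = float((g1[var] == 1).sum())
        c = float((g0[var] == 1).sum())
        t = TwoByTwo(a=a, b=c, c=float((g1[var] == 0).sum()), d=float((g0[var] == 0).sum()))
        or_, lo, hi, _ = odds_ratio_woolf(t)
        try:
            _, _, p = chi_square_test(np.array([[t.a, t.b], [t.c, t.d]]))
        except ValueError:
            p = np.nan
        rows.append(
            {
                "outcome": var, "type": "binary",
                "exposed_median": a, "exposed_q25": np.nan, "exposed_q75": np.nan,
                "control_median": c, "control_q25": np.nan, "control_q75": np.nan,
                "p_value": p, "odds_ratio": or_, "ci_low": lo, "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def charges_by_o2_quartile(
    records: pd.DataFrame,
    quartile_col: str = "o2_minute_bin",
    charge_col: str = "total_charges",
) -> pd.DataFrame:
    """Charge summary (median, quartiles, valid/total N) per oxygen quartile."""
    rows = []
    for q, grp in records.groupby(quartile_col):
        vals = grp[charge_col].dropna()
        rows.append(
            {
                "o2_quartile": q,
                "median": float(vals.median()) if len(vals) else np.nan,
                "q25": float(vals.quantile(0.25)) if len(vals) else np.nan,
                "q75": float(vals.quantile(0.75)) if len(vals) else np.nan,
                "valid_n": int(len(vals)),
                "total_n": int(len(grp)),
            }
        )
    return pd.DataFrame(rows)
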