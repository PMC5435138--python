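"""Descriptive / univariate statistics: 2x2 odds ratios with Woolf
confidence intervals, Pearson chi-square, t / Mann-Whitney comparisons,
and the missingness audit.

The odds ratio for a 2x2 table with cells a (outcome+, exposed),
b (outcome+, unexposed), c (outcome-, exposed), d (outcome-, unexposed) is
OR = (a/b)/(c/d), with the Woolf interval
exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).  When any cell is zero the
Haldane-Anscombe continuity correction (0.5 added to every cell) is
applied and the row is marked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TwoByTwo:
    """Counts: a=outcome+/exposed, b=outcome+/unexposed, c=outcome-/exposed, d=outcome-/unexposed."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


def odds_ratio_woolf(
    table: TwoByTwo, alpha: float = 0.05
) -> Tuple[Optional[float], Optional[float], Optional[float], bool]:
    """(OR, CI low, CI high, continuity_corrected).

    Returns (None, None, None, False) when a margin is empty and the OR is
    undefined even after correction.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = False
    if min(a, b, c, d) == 0:
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return None, None, None, False
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    return float(or_), float(lo), float(hi), corrected


def chi_square_test(table: np.ndarray) -> Tuple[float, int, float]:
    """Pearson chi-square (no continuity correction): (statistic, df, p).

    Zero-margin rows/columns are dropped with a warning before testing.
    """
    t = np.asarray(table, dtype=float)
    row_ok = t.sum(axis=1) > 0
    col_ok = t.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table", stacklevel=2)
        t = t[row_ok][:, col_ok]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table needs at least 2x2 non-empty margins")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def continuous_comparison(
    groups: Sequence[np.ndarray], method: str = "mann_whitney"
) -> Dict[str, object]:
    """Two-group comparison with Table-style summaries.

    method 't' uses Student's t (equal-variance); 'mann_whitney' the
    Mann-Whitney U with normal approximation.  Summaries are mean, median
    and IQR per group.  Constant pooled data yields p = 1 with a warning.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups expected")
    g1, g2 = (np.asarray(g, dtype=float) for g in groups)
    g1, g2 = g1[~np.isnan(g1)], g2[~np.isnan(g2)]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs n >= 2")
    summaries = [
        {
            "n": int(len(g)),
            "mean": float(np.mean(g)),
            "median": float(np.median(g)),
            "q25": float(np.percentile(g, 25)),
            "q75": float(np.percentile(g, 75)),
        }
        for g in (g1, g2)
    ]
    pooled = np.concatenate([g1, g2])
    if np.all(pooled == pooled[0]):
        warnings.warn("constant data in both groups; p set to 1", stacklevel=2)
        return {"method": method, "statistic": np.nan, "p": 1.0, "groups": summaries}
    if method == "t":
        stat, p = stats.ttest_ind(g1, g2, equal_var=True)
    elif method == "mann_whitney":
        stat, p = stats.mannwhitneyu(g1, g2, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"method": method, "statistic": float(stat), "p": float(p), "groups": summaries}


def missingness_audit(
    patients: pd.DataFrame,
    outcome_col: str = "early_prc",
    threshold: float = 0.05,
    exclude: Sequence[str] = ("patient_id",),
) -> pd.DataFrame:
    """Per-variable missingness with >threshold flags.

    For each flagged variable, an unadjusted 2x2 of outcome vs missingness
    (OR + Woolf CI) quantifies whether incomplete patients differ in
    outcome rate from complete ones.
    """
    rows: List[Dict[str, object]] = []
    y = patients[outcome_col].astype(float)
    for col in patients.columns:
        if col in exclude or col == outcome_col:
            continue
        miss = patients[col].isna()
        frac = float(miss.mean())
        row: Dict[str, object] = {
            "variable": col,
            "pct_missing": 100.0 * frac,
            "flagged": frac > threshold,
            "or_outcome_vs_missing": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
        }
        if row["flagged"]:
            t = TwoByTwo(
                a=float(((y == 1) & miss).sum()),
                b=float(((y == 1) & ~miss).sum()),
                c=float(((y == 0) & miss).sum()),
                d=float(((y == 0) & ~miss).sum()),
            )
            or_, lo, hi, _ = odds_ratio_woolf(t)
            row.update(or_outcome_vs_missing=or_, ci_low=lo, ci_high=hi)
        rows.append(row)
    return pd.DataFrame(rows)


def two_by_two_from_columns(
    patients: pd.DataFrame, exposure_col: str, outcome_col: str = "early_prc"
) -> TwoByTwo:
    """Build a 2x2 from binary columns on their joint non-missing rows."""
    sub = patients[[exposure_col, outcome_col]].dropna()
    e = sub[exposure_col].astype(float)
    y = sub[outcome_col].astype(float)
    return TwoByTwo(
        a=float(((y == 1) & (e == 1)).sum()),
        b=float(((y == 1) & (e == 0)).sum()),
        c=float(((y == 0) & (e == 1)).sum()),
        d=float(((y == 0) & (e == 0)).sum()),
    )


def table_one(
    patients: pd.DataFrame,
    binary_vars: Sequence[str],
    outcome_col: str = "early_prc",
) -> pd.DataFrame:
    """Frequency-distribution table across outcome groups.

    One row per binary variable: count (%) per outcome group on
    non-missing denominators, chi-square p, OR with Woolf 95% CI rendered
    to 1 decimal, and % missing.
    """
    rows = []
    y = patients[outcome_col].astype(float)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    for var in binary_vars:
        t = two_by_two_from_columns(patients, var, outcome_col)
        or_, lo, hi, corrected = odds_ratio_woolf(t)
        try:
            _, _, p = chi_square_test(np.array([[t.a, t.b], [t.c, t.d]]))
        except ValueError:
            p = np.nan
        pos_denom = t.a + t.b
        neg_denom = t.c + t.d
        rows.append(
            {
                "variable": var,
                "prc_count": int(t.a),
                "prc_pct": round(100.0 * t.a / pos_denom) if pos_denom else np.nan,
                "no_prc_count": int(t.c),
                "no_prc_pct": round(100.0 * t.c / neg_denom) if neg_denom else np.nan,
                "p_value": p,
                "odds_ratio": round(or_, 1) if or_ is not None else np.nan,
                "ci_low": round(lo, 1) if lo is not None else np.nan,
                "ci_high": round(hi, 1) if hi is not None else np.nan,
                "continuity_corrected": corrected,
                "pct_missing": 100.0 * float(patients[var].isna().mean()),
            }
        )
    return pd.DataFrame(rows)
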