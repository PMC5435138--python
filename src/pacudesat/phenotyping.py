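"""Population-centile thresholds and exposure assignment.

The four stream-level desaturation measures are dichotomized / ordinalized
against cohort-derived centile cutoffs: the 10th centile of per-patient
median SpO2 and of nadir SpO2 (lower tails carry the risk), the 90th
centile of desaturation duration, and quartiles of the oxygen-therapy
fraction.  Dose covariates (NMBA, morphine equivalents) are normalized per
ideal body weight per hour of anesthesia and flagged at their 75th
centile; anesthesia duration, anesthetic-depth duration and a surgical
complexity score get the same 75th-centile treatment.

Boundary conventions follow the operational definitions: strict ``<`` for
the nadir and median cuts, ``>=`` for the duration cut and every
75th-centile flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: default opioid -> morphine-equivalent factor per mg (editable assumption)
DEFAULT_OPIOID_CONVERSIONS = {"morphine": 1.0, "hydromorphone": 6.67, "fentanyl": 100.0}

NMBA_AGENTS = ("cisatracurium", "rocuronium", "vecuronium")


def quantile(values: Iterable[float], p: float) -> float:
    """Linear-interpolation quantile (position 1 + p(n-1) between order stats)."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        raise ValueError("quantile of empty input")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    return float(np.quantile(arr, p, method="linear"))


@dataclass
class PopulationThresholds:
    """Cohort-derived centile cutpoints; ``n_used`` records the non-missing n."""

    median_cut: Optional[float] = None          # 10th centile of per-patient medians
    duration_cut: Optional[float] = None        # 90th centile of min/hr below level
    nadir_cut: Optional[float] = None           # 10th centile of nadirs
    o2_quartile_bounds: Optional[Tuple[float, float, float]] = None
    nmba_high_dose_cuts: Dict[str, float] = field(default_factory=dict)
    opioid_dose_cut: Optional[float] = None
    mac_duration_cut: Optional[float] = None
    anesthesia_duration_cut: Optional[float] = None
    complexity_cut: Optional[float] = None
    n_used: Dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, object]:
        return {
            "median_cut": self.median_cut,
            "duration_cut": self.duration_cut,
            "nadir_cut": self.nadir_cut,
            "o2_quartile_bounds": list(self.o2_quartile_bounds) if self.o2_quartile_bounds else None,
            "nmba_high_dose_cuts": self.nmba_high_dose_cuts,
            "opioid_dose_cut": self.opioid_dose_cut,
            "mac_duration_cut": self.mac_duration_cut,
            "anesthesia_duration_cut": self.anesthesia_duration_cut,
            "complexity_cut": self.complexity_cut,
            "n_used": self.n_used,
        }


def _cut(series: pd.Series, p: float, name: str, thresholds: PopulationThresholds) -> Optional[float]:
    vals = series.dropna()
    thresholds.n_used[name] = int(len(vals))
    if len(vals) == 0:
        return None
    return quantile(vals.to_numpy(), p)


def derive_thresholds(
    measures: pd.DataFrame, records: Optional[pd.DataFrame] = None
) -> PopulationThresholds:
    """Centile cutpoints from the per-patient measures (and dose columns).

    Cuts are computed only over non-missing values; an all-missing measure
    leaves its cut absent and forces the downstream exposure missing.
    """
    th = PopulationThresholds()
    th.median_cut = _cut(measures["median_spo2"], 0.10, "median_cut", th)
    th.duration_cut = _cut(measures["minutes_below_level_per_hour"], 0.90, "duration_cut", th)
    th.nadir_cut = _cut(measures["nadir_spo2"], 0.10, "nadir_cut", th)
    frac = measures["o2_fraction"].dropna()
    th.n_used["o2_quartile_bounds"] = int(len(frac))
    if len(frac):
        th.o2_quartile_bounds = tuple(quantile(frac.to_numpy(), p) for p in (0.25, 0.50, 0.75))
    if records is not None:
        if "nmba_agent" in records and "nmba_dose_normalized" in records:
            for agent in NMBA_AGENTS:
                vals = records.loc[records["nmba_agent"] == agent, "nmba_dose_normalized"].dropna()
                if len(vals):
                    th.nmba_high_dose_cuts[agent] = quantile(vals.to_numpy(), 0.75)
                    th.n_used[f"nmba_cut_{agent}"] = int(len(vals))
        for col, attr in [
            ("morphine_equivalents_normalized", "opioid_dose_cut"),
            ("mac_above_1_min", "mac_duration_cut"),
            ("anesthesia_duration_min", "anesthesia_duration_cut"),
            ("complexity_score", "complexity_cut"),
        ]:
            if col in records:
                setattr(th, attr, _cut(records[col], 0.75, attr, th))
    return th


def ideal_body_weight(height_cm: float, sex: str) -> float:
    """Devine ideal body weight: 50 kg (male) / 45.5 kg (female) + 2.3 kg/inch over 60 in."""
    if not 100.0 <= height_cm <= 250.0:
        raise ValueError(f"height {height_cm} cm outside supported range [100, 250]")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    base = 50.0 if sex == "male" else 45.5
    inches = height_cm / 2.54
    return base + 2.3 * max(inches - 60.0, 0.0)


def normalize_nmba_dose(total_dose_mg: float, ibw_kg: float, anesthesia_duration_min: float) -> float:
    """Dose in mg per kg ideal body weight per hour of anesthesia."""
    if ibw_kg <= 0 or anesthesia_duration_min <= 0:
        raise ValueError("ideal body weight and anesthesia duration must be positive")
    return total_dose_mg / ibw_kg / (anesthesia_duration_min / 60.0)


def morphine_equivalents(
    administrations: Sequence[Tuple[str, float]],
    ibw_kg: float,
    anesthesia_duration_min: float,
    conversion_table: Optional[Mapping[str, float]] = None,
) -> float:
    """Total morphine-equivalent dose, normalized per IBW per hour."""
    table = DEFAULT_OPIOID_CONVERSIONS if conversion_table is None else conversion_table
    total = 0.0
    for agent, dose in administrations:
        if agent not in table:
            raise ValueError(f"no morphine-equivalent conversion for agent {agent!r}")
        total += dose * table[agent]
    return normalize_nmba_dose(total, ibw_kg, anesthesia_duration_min)


def surgical_complexity_score(
    records: pd.DataFrame,
    region_col: str = "procedure_region",
    outcome_col: str = "early_prc",
) -> Tuple[pd.Series, pd.Series, Optional[float]]:
    """Continuous procedure-risk score from a region-indicator logistic fit.

    Fits outcome ~ body-region indicators and uses each patient's fitted
    linear predictor as the score, dichotomized at its 75th centile with
    the >= convention.  Returns (score, high_flag, cut).  A single-region
    design is degenerate: the score is constant, nobody is flagged, and a
    warning is raised.
    """
    regions = records[region_col].astype(str)
    levels = sorted(regions.unique())
    if len(levels) < 2:
        warnings.warn("single procedure region: complexity score is degenerate", stacklevel=2)
        score = pd.Series(0.0, index=records.index)
        return score, pd.Series(False, index=records.index), None
    X = pd.get_dummies(regions, drop_first=True).astype(float)
    X = sm.add_constant(X, has_constant="add")
    y = records[outcome_col].astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", False) or np.abs(fit.params).max() > 15:
            raise np.linalg.LinAlgError
        score = pd.Series(np.asarray(X @ fit.params), index=records.index)
    except (np.linalg.LinAlgError, ValueError):
        # the region-indicator model is saturated, so its ML linear
        # predictor is each region's empirical log-odds; when a region has
        # zero outcome variation the ML estimate diverges and we use the
        # continuity-corrected empirical log-odds instead
        warnings.warn(
            "separation in complexity-score fit; using continuity-corrected "
            "empirical log-odds per region",
            stacklevel=2,
        )
        grp = records.groupby(regions)[outcome_col]
        logodds = np.log((grp.sum() + 0.5) / (grp.count() - grp.sum() + 0.5))
        score = regions.map(logodds).astype(float)
    cut = quantile(score.to_numpy(), 0.75)
    return score, score >= cut, cut


def o2_quartile(fraction: float, bounds: Tuple[float, float, float]) -> int:
    """Ordinal 1-4 from the fraction quartile bounds (ties promote upward)."""
    return 1 + int(sum(fraction >= b for b in bounds))


def o2_minute_bin(o2_duration_min: float) -> int:
    """The fixed minute rendering of the quartiles for a 120-min stay:
    <=30, 31-60, 61-90, >90 minutes."""
    return 1 + int(np.digitize(o2_duration_min, [30.0, 60.0, 90.0], right=False))


def assign_exposures(
    measures: pd.DataFrame,
    thresholds: PopulationThresholds,
    records: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """ExposureProfile table: dichotomized/ordinalized modeling exposures.

    nadir_low and median_low use strict ``<`` against their cuts;
    duration_high uses ``>=``; the oxygen quartile is 1-4 from the fraction
    bounds.  Missing measures produce missing exposures (audited upstream).
    """
    out = pd.DataFrame({"patient_id": measures["patient_id"]})

    def _flag(col: str, cutv: Optional[float], op: str) -> pd.Series:
        vals = measures[col]
        if cutv is None:
            return pd.Series(np.nan, index=measures.index)
        res = vals < cutv if op == "<" else vals >= cutv
        return res.astype(float).where(vals.notna())

    out["nadir_low"] = _flag("nadir_spo2", thresholds.nadir_cut, "<")
    out["median_low"] = _flag("median_spo2", thresholds.median_cut, "<")
    out["duration_high"] = _flag("minutes_below_level_per_hour", thresholds.duration_cut, ">=")
    if thresholds.o2_quartile_bounds is not None:
        out["o2_quartile"] = measures["o2_fraction"].map(
            lambda f: o2_quartile(f, thresholds.o2_quartile_bounds) if pd.notna(f) else np.nan
        )
    else:
        out["o2_quartile"] = np.nan
    out["o2_minute_bin"] = measures["o2_duration_min"].map(
        lambda d: o2_minute_bin(d) if pd.notna(d) else np.nan
    )

    if records is not None:
        rec = records.set_index("patient_id").loc[out["patient_id"]].reset_index()
        if "nmba_dose_normalized" in rec and thresholds.nmba_high_dose_cuts:
            flags = np.zeros(len(rec))
            for agent, cutv in thresholds.nmba_high_dose_cuts.items():
                mask = (rec["nmba_agent"] == agent) & rec["nmba_dose_normalized"].notna()
                flags[mask.to_numpy()] = (
                    rec.loc[mask, "nmba_dose_normalized"] >= cutv
                ).astype(float)
            out["high_dose_nmba"] = flags
        for col, cutv, name in [
            ("morphine_equivalents_normalized", thresholds.opioid_dose_cut, "opioid_high"),
            ("mac_above_1_min", thresholds.mac_duration_cut, "mac_high"),
            ("anesthesia_duration_min", thresholds.anesthesia_duration_cut, "anesthesia_long"),
            ("complexity_score", thresholds.complexity_cut, "high_risk_surgery_score"),
        ]:
            if col in rec and cutv is not None:
                out[name] = (rec[col] >= cutv).astype(float).where(rec[col].notna())
    return out
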