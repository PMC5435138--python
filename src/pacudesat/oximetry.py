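"""Per-patient desaturation metrics from per-minute PACU SpO2 streams.

Four measures are computed for each patient:

* central tendency — the median of all 5-minute sliding-window medians,
  over the first 120 monitored minutes;
* duration of desaturation — minutes per monitored hour spent below a
  threshold level, over the same censored span;
* nadir — the lowest valid SpO2 over the whole stay, including manual
  room-air entries charted during oxygen-off epochs of at least 5 minutes;
* oxygen exposure — minutes of documented oxygen therapy and the fraction
  of the stay they cover, over the whole stay.

Values below a 60% artifact floor are treated as sensor artifacts and set
missing everywhere.  Central tendency and duration are censored at the
first 120 minutes; nadir and oxygen exposure deliberately are not, since
they are defined through to PACU discharge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
MANUAL_ROOM_AIR = "manual_room_air"

#: reason codes for missing measures
REASON_ARTIFACT = "artifact"
REASON_INSUFFICIENT = "insufficient_data"


@dataclass
class OximetryStream:
    """One patient's ordered per-minute SpO2 record in PACU.

    ``spo2`` uses NaN for missing; ``minute`` is 0-based from PACU
    admission.  Continuous samples must have strictly increasing minute
    indices; manual room-air entries may share a minute with a continuous
    sample and always carry ``o2_flag = False``.
    """

    patient_id: str
    minute: np.ndarray
    spo2: np.ndarray
    o2_flag: np.ndarray
    source: np.ndarray
    pacu_duration_min: int

    def __post_init__(self) -> None:
        self.minute = np.asarray(self.minute, dtype=int)
        self.spo2 = np.asarray(self.spo2, dtype=float)
        self.o2_flag = np.asarray(self.o2_flag, dtype=bool)
        self.source = np.asarray(self.source, dtype=object)
        cont = self.continuous_mask
        mins = self.minute[cont]
        if mins.size and np.any(np.diff(mins) <= 0):
            raise ValueError(f"{self.patient_id}: continuous minutes must be strictly increasing")
        if np.any(self.o2_flag[~cont]):
            raise ValueError(f"{self.patient_id}: manual room-air entries cannot carry o2_flag")
        if mins.size and self.pacu_duration_min < mins.max():
            raise ValueError(f"{self.patient_id}: pacu_duration_min below last minute index")

    @property
    def continuous_mask(self) -> np.ndarray:
        return self.source == CONTINUOUS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "minute": self.minute,
                "spo2": self.spo2,
                "o2_flag": self.o2_flag.astype(int),
                "source": self.source,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, pacu_duration_min: Optional[int] = None) -> "OximetryStream":
        pid = str(frame["patient_id"].iloc[0])
        dur = pacu_duration_min if pacu_duration_min is not None else int(frame["minute"].max()) + 1
        return cls(
            patient_id=pid,
            minute=frame["minute"].to_numpy(),
            spo2=frame["spo2"].to_numpy(dtype=float),
            o2_flag=frame["o2_flag"].to_numpy().astype(bool),
            source=frame["source"].to_numpy(dtype=object),
            pacu_duration_min=dur,
        )


@dataclass
class DesatMeasures:
    """The per-patient desaturation measures, with missing-reason codes."""

    patient_id: str
    median_spo2: Optional[float] = None
    minutes_below_level_per_hour: Optional[float] = None
    nadir_spo2: Optional[float] = None
    o2_duration_min: Optional[float] = None
    o2_fraction: Optional[float] = None
    monitored_minutes: Optional[float] = None
    missing_reasons: Dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, object]:
        d = {
            "patient_id": self.patient_id,
            "median_spo2": self.median_spo2,
            "minutes_below_level_per_hour": self.minutes_below_level_per_hour,
            "nadir_spo2": self.nadir_spo2,
            "o2_duration_min": self.o2_duration_min,
            "o2_fraction": self.o2_fraction,
            "monitored_minutes": self.monitored_minutes,
        }
        return d


def censor_and_clean(
    stream: OximetryStream, max_minutes: int = 120, artifact_floor: float = 60.0
) -> OximetryStream:
    """Apply the censoring and artifact rules, returning a new stream.

    Continuous samples are truncated to minutes [0, max_minutes); values
    below the artifact floor (any source) are set missing.  Manual entries
    are retained regardless of minute as long as they fall within the stay.
    Cleaning is total: no input is rejected.
    """
    cont = stream.continuous_mask
    keep = ~cont | ((stream.minute >= 0) & (stream.minute < max_minutes))
    in_stay = stream.minute <= stream.pacu_duration_min
    keep &= in_stay
    spo2 = stream.spo2[keep].copy()
    spo2[spo2 < artifact_floor] = np.nan
    return OximetryStream(
        patient_id=stream.patient_id,
        minute=stream.minute[keep],
        spo2=spo2,
        o2_flag=stream.o2_flag[keep],
        source=stream.source[keep],
        pacu_duration_min=stream.pacu_duration_min,
    )


def _continuous_grid(stream: OximetryStream, span: int) -> np.ndarray:
    """SpO2 on a dense minute grid [0, span), NaN where unobserved/missing."""
    grid = np.full(span, np.nan)
    cont = stream.continuous_mask
    mins = stream.minute[cont]
    vals = stream.spo2[cont]
    ok = (mins >= 0) & (mins < span)
    grid[mins[ok]] = vals[ok]
    return grid


def sliding_window_medians(
    stream: OximetryStream,
    window: int = 5,
    step: int = 1,
    max_minutes: int = 120,
    artifact_floor: float = 60.0,
    min_valid: Optional[int] = None,
) -> np.ndarray:
    """Medians of each w-minute sliding window over the censored span.

    A window position contributes only when it holds at least
    ``ceil(window / 2)`` non-missing samples (configurable through
    ``min_valid``), so near-empty windows never produce a "median".
    Returns an empty array when no window qualifies.
    """
    if min_valid is None:
        min_valid = math.ceil(window / 2)
    clean = censor_and_clean(stream, max_minutes=max_minutes, artifact_floor=artifact_floor)
    span = min(max_minutes, clean.pacu_duration_min)
    grid = _continuous_grid(clean, span)
    last = int(clean.minute[clean.continuous_mask].max()) + 1 if clean.continuous_mask.any() else 0
    span = min(span, last)
    meds = []
    for start in range(0, span - window + 1, step):
        win = grid[start : start + window]
        vals = win[~np.isnan(win)]
        if vals.size >= min_valid:
            meds.append(float(np.median(vals)))
    return np.asarray(meds)


def median_spo2(stream: OximetryStream, **kwargs) -> Optional[float]:
    """Median of all sliding-window medians; None when no window qualifies."""
    meds = sliding_window_medians(stream, **kwargs)
    if meds.size == 0:
        return None
    return float(np.median(meds))


def minutes_below_level(
    stream: OximetryStream,
    level: float,
    max_minutes: int = 120,
    artifact_floor: float = 60.0,
) -> Optional[float]:
    """Minutes per monitored hour with SpO2 strictly below ``level``.

    Computed over non-missing continuous minutes of the censored span:
    ``60 * n_below / n_monitored``.  None when nothing was monitored.
    """
    clean = censor_and_clean(stream, max_minutes=max_minutes, artifact_floor=artifact_floor)
    cont = clean.continuous_mask
    vals = clean.spo2[cont]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return None
    return 60.0 * float(np.sum(vals < level)) / float(vals.size)


def _o2_off_run_lengths(stream: OximetryStream) -> Dict[int, int]:
    """Map each oxygen-off continuous minute to the length of its off-run."""
    cont = stream.continuous_mask
    mins = stream.minute[cont]
    flags = stream.o2_flag[cont]
    out: Dict[int, int] = {}
    run: list[int] = []
    prev = None
    for m, f in zip(mins, flags):
        contiguous = prev is not None and m == prev + 1
        if not f and (run and contiguous):
            run.append(int(m))
        elif not f:
            for r in run:
                out[r] = len(run)
            run = [int(m)]
        else:
            for r in run:
                out[r] = len(run)
            run = []
        prev = m
    for r in run:
        out[r] = len(run)
    return out


def nadir_spo2(
    stream: OximetryStream,
    artifact_floor: float = 60.0,
    min_roomair_epoch: int = 5,
    full_stay: bool = True,
    max_minutes: int = 120,
) -> Optional[float]:
    """Lowest valid SpO2 for the patient.

    Candidates are (i) all non-missing continuous samples — through to PACU
    discharge when ``full_stay`` (the default), else censored at
    ``max_minutes`` — and (ii) manual room-air entries whose surrounding
    oxygen-off epoch lasts at least ``min_roomair_epoch`` minutes.  The
    artifact floor applies to both.
    """
    span = stream.pacu_duration_min if full_stay else max_minutes
    cont = stream.continuous_mask
    in_span = stream.minute < span
    cand = stream.spo2[cont & in_span]
    cand = cand[~np.isnan(cand)]
    cand = cand[cand >= artifact_floor]
    candidates = list(cand)

    off_runs = _o2_off_run_lengths(stream)
    for m, v, src in zip(stream.minute, stream.spo2, stream.source):
        if src != MANUAL_ROOM_AIR or np.isnan(v) or v < artifact_floor or m >= span:
            continue
        if off_runs.get(int(m), 0) >= min_roomair_epoch:
            candidates.append(float(v))
    if not candidates:
        return None
    return float(min(candidates))


def oxygen_exposure(stream: OximetryStream) -> tuple[float, float]:
    """(minutes of documented oxygen therapy, fraction of the PACU stay).

    Counted over the full stay — oxygen weaning after the censoring horizon
    is part of the phenotype.
    """
    if stream.pacu_duration_min <= 0:
        raise ValueError("pacu_duration_min must be positive")
    cont = stream.continuous_mask
    duration = float(np.sum(stream.o2_flag[cont]))
    return duration, duration / float(stream.pacu_duration_min)


def compute_measures(
    stream: OximetryStream,
    level: float = 94.0,
    window: int = 5,
    max_minutes: int = 120,
    artifact_floor: float = 60.0,
    nadir_full_stay: bool = True,
) -> DesatMeasures:
    """All four desaturation measures for one patient."""
    m = DesatMeasures(patient_id=stream.patient_id)
    clean = censor_and_clean(stream, max_minutes=max_minutes, artifact_floor=artifact_floor)
    cont_vals = clean.spo2[clean.continuous_mask]
    m.monitored_minutes = float(np.sum(~np.isnan(cont_vals)))

    med = median_spo2(stream, window=window, max_minutes=max_minutes, artifact_floor=artifact_floor)
    if med is None:
        m.missing_reasons["median_spo2"] = REASON_INSUFFICIENT
    m.median_spo2 = med

    below = minutes_below_level(stream, level, max_minutes=max_minutes, artifact_floor=artifact_floor)
    if below is None:
        m.missing_reasons["minutes_below_level_per_hour"] = REASON_INSUFFICIENT
    m.minutes_below_level_per_hour = below

    nadir = nadir_spo2(
        stream, artifact_floor=artifact_floor, full_stay=nadir_full_stay, max_minutes=max_minutes
    )
    if nadir is None:
        m.missing_reasons["nadir_spo2"] = REASON_INSUFFICIENT
    m.nadir_spo2 = nadir

    m.o2_duration_min, m.o2_fraction = oxygen_exposure(stream)
    return m


def measures_table(
    streams: Sequence[OximetryStream], level: float = 94.0, **kwargs
) -> pd.DataFrame:
    """Per-patient DesatMeasures for a cohort, as a DataFrame."""
    rows = [compute_measures(s, level=level, **kwargs).as_dict() for s in streams]
    return pd.DataFrame(rows)
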