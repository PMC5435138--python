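"""Synthetic PACU cohort generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be validated against a known data-generating
mechanism:

* per-minute SpO2 streams with episodic desaturation events (homogeneous
  Poisson onsets, exponential durations, Gaussian depths, clipped at the
  60% floor) and a nurse oxygen-response mechanism: once SpO2 has been
  below the alarm threshold for a configurable number of consecutive
  minutes, oxygen is applied (adding a configurable uplift) and stays on
  through the event plus a washout period;
* manual room-air SpO2 entries charted with a configured probability
  during oxygen-off epochs of at least five minutes;
* binary covariates at configured prevalences, a logistic outcome model
  with known coefficients on the latent OSA-risk phenotype and covariates,
  and log-normal charges by oxygen-duration stratum.

Event onsets are built from a fixed sequence of Exp(1) gaps divided by the
stratum rate, so that for a fixed substream raising the event rate adds
events without reshuffling earlier ones.  One master seed spawns
per-patient substreams by stable hashing of the patient id, so cohort
size changes do not reshuffle existing patients.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PHENOTYPES, SimulationConfig
from .oximetry import CONTINUOUS, MANUAL_ROOM_AIR, OximetryStream


@dataclass
class PatientTruth:
    phenotype: str
    event_onsets: List[float]
    event_durations: List[float]
    event_depths: List[float]
    linear_predictor: float
    outcome_probability: float


@dataclass
class SyntheticTruth:
    """Latent generating state, emitted alongside the data.

    Never consumed by analysis modules; exists so parameter-recovery tests
    can compare estimates to the generating mechanism.
    """

    seed: int
    coefficients: Dict[str, float]
    patients: Dict[str, PatientTruth] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "coefficients": self.coefficients,
            "patients": {k: dataclasses.asdict(v) for k, v in self.patients.items()},
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        return cls(
            seed=payload["seed"],
            coefficients=payload["coefficients"],
            patients={k: PatientTruth(**v) for k, v in payload["patients"].items()},
        )


def substream_seed(master_seed: int, patient_id: str) -> int:
    """Stable per-patient substream key from the master seed and id."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(patient_id.encode())])
    return int(ss.generate_state(1, np.uint64)[0]) % (2**31)


def _event_process(
    rng: np.random.Generator, rate_per_hour: float, span_min: float, config: SimulationConfig
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Poisson event onsets/durations/depths over [0, span_min) minutes.

    Gaps are a fixed block of Exp(1) draws scaled by 1/rate, so the event
    set grows monotonically with the rate for a fixed generator state.
    """
    block = 512
    gaps = rng.exponential(1.0, size=block)
    durations = rng.exponential(config.event_duration_mean, size=block)
    depths = np.clip(rng.normal(config.event_depth_mean, config.event_depth_sd, size=block), 0.0, None)
    if rate_per_hour <= 0:
        return np.empty(0), np.empty(0), np.empty(0)
    onsets = np.cumsum(gaps) * 60.0 / rate_per_hour
    keep = onsets < span_min
    return onsets[keep], durations[keep], depths[keep]


def generate_stream(
    phenotype: str, config: SimulationConfig, substream_seed: int, patient_id: str = "P0"
) -> Tuple[OximetryStream, PatientTruth]:
    """One patient's PACU SpO2 stream plus its latent truth.

    The displayed trace is baseline Gaussian noise minus the deepest active
    event, plus the oxygen uplift while therapy is on, rounded to integer
    percent and clipped to [60, 100].
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}")
    ss = np.random.SeedSequence(substream_seed)
    rng_stay, rng_events, rng_noise, rng_manual, rng_o2 = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    span = config.pacu_duration_min
    if config.short_stay_probability > 0 and rng_stay.random() < config.short_stay_probability:
        span = int(rng_stay.integers(config.min_short_stay_min, config.pacu_duration_min))

    rate = config.event_rate_by_phenotype[phenotype]
    onsets, durations, depths = _event_process(rng_events, rate, span, config)

    t = np.arange(span, dtype=float)
    offset = (
        rng_noise.normal(0.0, config.baseline_between_sd)
        if config.baseline_between_sd > 0
        else 0.0
    )
    raw = config.baseline_spo2_mean + offset + (
        rng_noise.normal(0.0, config.baseline_spo2_sd, size=span)
        if config.baseline_spo2_sd > 0
        else np.zeros(span)
    )
    drop = np.zeros(span)
    for o, d, dep in zip(onsets, durations, depths):
        active = (t >= o) & (t < o + d)
        drop[active] = np.maximum(drop[active], dep)
    raw = raw - drop

    # Nurse response: runs of sub-alarm minutes of length >= delay switch
    # oxygen on from (run start + delay) through run end + washout.
    below = raw < config.alarm_threshold
    o2 = np.zeros(span, dtype=bool)
    i = 0
    while i < span:
        if below[i]:
            j = i
            while j < span and below[j]:
                j += 1
            delay = config.nurse_response_delay
            if j - i >= delay and i + delay < span:
                o2[i + delay : min(j + config.o2_washout_min, span)] = True
            i = j
        else:
            i += 1

    # prophylactic oxygen from admission, independent of events
    if config.prophylactic_o2_probability > 0 and rng_o2.random() < config.prophylactic_o2_probability:
        d = int(rng_o2.integers(config.prophylactic_o2_min, span + 1)) if span > config.prophylactic_o2_min else span
        o2[:d] = True

    displayed = raw + np.where(o2, config.o2_uplift, 0.0)
    displayed = np.clip(np.rint(displayed), 60, 100)

    minutes = list(range(span))
    spo2 = list(displayed)
    flags = list(o2)
    sources = [CONTINUOUS] * span

    # Manual room-air entries during oxygen-off epochs of >= 5 minutes.
    epoch_start = None
    epochs = []
    for m in range(span + 1):
        off = m < span and not o2[m]
        if off and epoch_start is None:
            epoch_start = m
        elif not off and epoch_start is not None:
            epochs.append((epoch_start, m))
            epoch_start = None
    for a, b in epochs:
        if b - a >= 5 and rng_manual.random() < config.manual_roomair_probability:
            m = int(rng_manual.integers(a, b))
            minutes.append(m)
            spo2.append(displayed[m])
            flags.append(False)
            sources.append(MANUAL_ROOM_AIR)

    stream = OximetryStream(
        patient_id=patient_id,
        minute=np.asarray(minutes),
        spo2=np.asarray(spo2, dtype=float),
        o2_flag=np.asarray(flags),
        source=np.asarray(sources, dtype=object),
        pacu_duration_min=span,
    )
    truth = PatientTruth(
        phenotype=phenotype,
        event_onsets=[float(x) for x in onsets],
        event_durations=[float(x) for x in durations],
        event_depths=[float(x) for x in depths],
        linear_predictor=float("nan"),
        outcome_probability=float("nan"),
    )
    return stream, truth


def _draw_covariates(rng: np.random.Generator, config: SimulationConfig, n: int) -> pd.DataFrame:
    cols = {}
    for name, p in config.covariate_prevalences.items():
        cols[name] = (rng.random(n) < p).astype(int)
    return pd.DataFrame(cols)


_REGION_WEIGHTS = {
    "head": 0.12, "neck": 0.10, "intrathoracic": 0.05, "upper_abdomen": 0.14,
    "lower_abdomen": 0.20, "extremity": 0.24, "perineum": 0.12, "spine": 0.03,
}


def generate_cohort(
    config: SimulationConfig,
) -> Tuple[List[OximetryStream], pd.DataFrame, SyntheticTruth]:
    """Streams, a one-row-per-patient table, and the latent truth object.

    Outcome is drawn from the configured logistic model on the latent
    OSA-risk phenotype and covariates; charges are log-normal with
    parameters chosen by the realized oxygen-duration stratum.
    """
    n = config.n_patients
    master = np.random.default_rng(config.seed)
    ids = [f"P{i:06d}" for i in range(n)]

    phen_names = list(PHENOTYPES)
    phen_p = [config.phenotype_probabilities[k] for k in phen_names]
    phenotypes = master.choice(phen_names, size=n, p=phen_p)

    cov = _draw_covariates(master, config, n)
    cov.insert(0, "patient_id", ids)

    # demographics / dosing attributes used by the phenotyping module
    sex = np.where(master.random(n) < 0.5, "male", "female")
    height = np.where(sex == "male", master.normal(176, 7, n), master.normal(163, 7, n))
    height = np.clip(height, 120, 210)
    age = np.clip(master.normal(55, 15, n), 18, 95).round(0)
    weight = np.clip(master.normal(82, 18, n), 40, 180).round(1)
    anes_dur = np.clip(master.lognormal(np.log(120), 0.5, n), 20, 720).round(0)
    mac_min = np.clip(anes_dur * master.beta(4, 2, n), 0, None).round(0)
    agents = master.choice(
        ["none", "cisatracurium", "rocuronium", "vecuronium"], size=n, p=[0.39, 0.06, 0.05, 0.50]
    )
    nmba_dose = np.where(
        agents == "none", 0.0, np.clip(master.lognormal(np.log(8), 0.6, n), 0.5, 80)
    ).round(2)
    morphine = np.where(master.random(n) < 0.27, master.lognormal(np.log(6), 0.5, n), 0.0).round(2)
    fentanyl_mg = np.where(master.random(n) < 0.93, master.lognormal(np.log(0.15), 0.5, n), 0.0).round(4)
    regions = master.choice(list(_REGION_WEIGHTS), size=n, p=list(_REGION_WEIGHTS.values()))

    streams: List[OximetryStream] = []
    truth = SyntheticTruth(seed=config.seed, coefficients=dict(config.outcome_coefficients))
    o2_minutes = np.zeros(n)
    for i, pid in enumerate(ids):
        stream, ptruth = generate_stream(
            phenotypes[i], config, substream_seed(config.seed, pid), patient_id=pid
        )
        streams.append(stream)
        o2_minutes[i] = float(np.sum(stream.o2_flag[stream.continuous_mask]))
        truth.patients[pid] = ptruth

    # logistic outcome on latent phenotype + covariates
    lp = np.full(n, config.outcome_coefficients["intercept"])
    for term, beta in config.outcome_coefficients.items():
        if term == "intercept":
            continue
        if term == "phenotype_moderate":
            lp += beta * (phenotypes == "moderate")
        elif term == "phenotype_high":
            lp += beta * (phenotypes == "high")
        else:
            lp += beta * cov[term].to_numpy()
    p_outcome = 1.0 / (1.0 + np.exp(-lp))
    outcome = (master.random(n) < p_outcome).astype(int)
    for i, pid in enumerate(ids):
        truth.patients[pid].linear_predictor = float(lp[i])
        truth.patients[pid].outcome_probability = float(p_outcome[i])

    # charges by realized oxygen-duration stratum (minute bins of a 120-min stay)
    stratum = np.digitize(o2_minutes, [30.0, 60.0, 90.0], right=True)
    mus = np.array([c.mu for c in config.charge_lognormal_params])[stratum]
    sigmas = np.array([c.sigma for c in config.charge_lognormal_params])[stratum]
    total = master.lognormal(mus, sigmas).round(2)
    dos = (total * np.clip(master.beta(8, 2, n), 0.05, 1.0)).round(2)
    surg = (total * np.clip(master.beta(5, 4, n), 0.0, 1.0)).round(2)
    resp = np.where(
        master.random(n) < 0.15 + 0.1 * (stratum >= 2), master.lognormal(5.0, 1.0, n), 0.0
    ).round(2)
    los = master.poisson(0.4 + 0.2 * stratum)
    vent = (master.random(n) < (0.005 + 0.01 * (stratum >= 2))).astype(int)

    patients = cov.copy()
    patients["sex"] = sex
    patients["age"] = age
    patients["height_cm"] = height.round(1)
    patients["weight_kg"] = weight
    patients["anesthesia_duration_min"] = anes_dur
    patients["mac_above_1_min"] = mac_min
    patients["nmba_agent"] = agents
    patients["nmba_dose_mg"] = nmba_dose
    patients["morphine_mg"] = morphine
    patients["fentanyl_mg"] = fentanyl_mg
    patients["procedure_region"] = regions
    patients["early_prc"] = outcome
    patients["reintubation"] = outcome
    patients["vent_support"] = np.maximum(vent, outcome)
    patients["total_charges"] = total
    patients["day_of_surgery_charges"] = dos
    patients["surgery_charges"] = surg
    patients["respiratory_charges"] = resp
    patients["hospital_los_days"] = los
    return streams, patients, truth


def simulate_logistic_cohort(
    n: int,
    coefficients: Dict[str, float],
    covariate_prevalences: Dict[str, float],
    seed: int,
    exposure_name: str = "exposure",
    exposure_model: Optional[Dict[str, float]] = None,
) -> pd.DataFrame:
    """Patient-level fast path: covariates, exposure and outcome only.

    Draws binary covariates at the configured prevalences, an exposure from
    a logistic model on the covariates (``exposure_model``, keyed by
    covariate name plus 'intercept' — this is how confounding is planted),
    and the outcome from ``coefficients`` (keyed by 'intercept', the
    exposure name, and covariate names).  Used by simulation studies where
    rendering per-minute streams adds nothing.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {name: (rng.random(n) < p).astype(int) for name, p in covariate_prevalences.items()}
    )
    if exposure_model is None:
        exposure_model = {"intercept": 0.0}
    lp_x = np.full(n, exposure_model.get("intercept", 0.0))
    for term, beta in exposure_model.items():
        if term == "intercept":
            continue
        if term not in df.columns:
            raise ValueError(f"exposure model references unknown covariate {term!r}")
        lp_x += beta * df[term].to_numpy()
    df[exposure_name] = (rng.random(n) < 1.0 / (1.0 + np.exp(-lp_x))).astype(int)

    lp_y = np.full(n, coefficients["intercept"])
    for term, beta in coefficients.items():
        if term == "intercept":
            continue
        if term not in df.columns:
            raise ValueError(f"outcome coefficient references unknown term {term!r}")
        lp_y += beta * df[term].to_numpy()
    df["outcome"] = (rng.random(n) < 1.0 / (1.0 + np.exp(-lp_y))).astype(int)
    return df


def streams_to_frame(streams: Sequence[OximetryStream]) -> pd.DataFrame:
    """Long-format oximetry table (patient_id, minute, spo2, o2_flag, source)."""
    return pd.concat([s.to_frame() for s in streams], ignore_index=True)


def frame_to_streams(frame: pd.DataFrame) -> List[OximetryStream]:
    out = []
    for pid, grp in frame.groupby("patient_id", sort=True):
        cont = grp[grp["source"] == CONTINUOUS]
        dur = int(cont["minute"].max()) + 1 if len(cont) else int(grp["minute"].max()) + 1
        out.append(OximetryStream.from_frame(grp.reset_index(drop=True), pacu_duration_min=dur))
    return out
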