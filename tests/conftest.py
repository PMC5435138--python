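from __future__ import annotations

import numpy as np
import pytest

from pacudesat.oximetry import CONTINUOUS, MANUAL_ROOM_AIR, OximetryStream


def make_stream(
    spo2,
    patient_id="P0",
    o2_flags=None,
    manual=(),
    start=0,
    stay=None,
):
    """Continuous stream from a value list plus optional manual entries.

    ``manual`` is a sequence of (minute, value) room-air entries appended
    after the continuous block; ``None`` values become missing samples.
    """
    vals = [np.nan if v is None else float(v) for v in spo2]
    n = len(vals)
    minutes = list(range(start, start + n))
    flags = list(o2_flags) if o2_flags is not None else [False] * n
    sources = [CONTINUOUS] * n
    for m, v in manual:
        minutes.append(m)
        vals.append(float(v))
        flags.append(False)
        sources.append(MANUAL_ROOM_AIR)
    return OximetryStream(
        patient_id=patient_id,
        minute=np.asarray(minutes),
        spo2=np.asarray(vals, dtype=float),
        o2_flag=np.asarray(flags),
        source=np.asarray(sources, dtype=object),
        pacu_duration_min=stay if stay is not None else start + n,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stream(rng, patient_id="R0", max_len=200):
    """Random stream for oracle-equivalence checks: variable stay length,
    scattered missing values, artifacts, oxygen runs, manual entries."""
    stay = int(rng.integers(10, max_len + 1))
    vals = rng.normal(95, 4, stay)
    vals[rng.random(stay) < 0.05] = np.nan            # dropouts
    art = rng.random(stay) < 0.03
    vals[art] = rng.uniform(20, 59, art.sum())        # artifacts below floor
    flags = np.zeros(stay, dtype=bool)
    k = int(rng.integers(0, 3))
    for _ in range(k):
        a = int(rng.integers(0, stay))
        b = min(stay, a + int(rng.integers(1, 40)))
        flags[a:b] = True
    minutes = np.arange(stay)
    keep = rng.random(stay) < 0.97                    # occasional unrecorded minute
    manual = []
    for _ in range(int(rng.integers(0, 3))):
        m = int(rng.integers(0, stay))
        manual.append((m, float(np.round(rng.uniform(55, 99)))))
    stream_vals = [None if (not keep[t] or np.isnan(vals[t])) else float(np.round(vals[t])) for t in range(stay)]
    # build with only kept minutes
    kept_minutes = [t for t in range(stay) if keep[t]]
    arr_vals = [np.nan if stream_vals[t] is None else stream_vals[t] for t in kept_minutes]
    from pacudesat.oximetry import CONTINUOUS as C, MANUAL_ROOM_AIR as M
    from pacudesat.oximetry import OximetryStream as S

    mins = kept_minutes + [m for m, _ in manual]
    sp = arr_vals + [v for _, v in manual]
    fl = [bool(flags[t]) for t in kept_minutes] + [False] * len(manual)
    src = [C] * len(kept_minutes) + [M] * len(manual)
    stream = S(
        patient_id=patient_id,
        minute=np.asarray(mins),
        spo2=np.asarray(sp, dtype=float),
        o2_flag=np.asarray(fl),
        source=np.asarray(src, dtype=object),
        pacu_duration_min=stay,
    )
    cont = {t: (None if stream_vals[t] is None else stream_vals[t]) for t in kept_minutes}
    o2_on = {t: bool(flags[t]) for t in kept_minutes}
    return stream, cont, manual, o2_on, stay
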