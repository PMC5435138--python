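"""Independent brute-force oracles used across the test suite.

Everything here is written from the definitions, in plain Python loops,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple


def naive_median(values: Sequence[float]) -> float:
    s = sorted(values)
    n = len(s)
    if n % 2 == 1:
        return float(s[n // 2])
    return (s[n // 2 - 1] + s[n // 2]) / 2.0


def naive_window_medians(
    grid: Sequence[Optional[float]], window: int = 5, min_valid: Optional[int] = None
) -> List[float]:
    """grid[t] = spo2 at minute t (None = missing), already censored/cleaned."""
    if min_valid is None:
        min_valid = math.ceil(window / 2)
    out = []
    for start in range(len(grid) - window + 1):
        vals = [v for v in grid[start : start + window] if v is not None]
        if len(vals) >= min_valid:
            out.append(naive_median(vals))
    return out


def naive_stream_metrics(
    cont: Dict[int, Optional[float]],
    manual: List[Tuple[int, float]],
    o2_on: Dict[int, bool],
    stay: int,
    level: float,
    max_minutes: int = 120,
    floor: float = 60.0,
    window: int = 5,
) -> Dict[str, Optional[float]]:
    """All four measures from raw per-minute data, by definition.

    cont: minute -> spo2 (None missing) for continuous samples;
    manual: (minute, spo2) room-air entries; o2_on: minute -> oxygen flag
    for continuous minutes; stay: PACU duration in minutes.
    """
    def clean(v):
        return None if v is None or v < floor else v

    # censored grid for central tendency / duration
    span = min(max_minutes, stay)
    grid = [clean(cont.get(t)) if t in cont else None for t in range(span)]
    observed = [t for t in range(span) if t in cont]
    if observed:
        grid = grid[: max(observed) + 1]
    meds = naive_window_medians(grid, window=window)
    median_spo2 = naive_median(meds) if meds else None

    monitored = [v for v in grid if v is not None]
    if monitored:
        below = sum(1 for v in monitored if v < level)
        minutes_below = 60.0 * below / len(monitored)
    else:
        minutes_below = None

    # nadir over the full stay + qualifying manual entries
    cands = [clean(v) for t, v in cont.items() if t < stay and clean(v) is not None]
    for t, v in manual:
        if t >= stay or clean(v) is None:
            continue
        # length of the o2-off run of consecutive continuous minutes around t
        if o2_on.get(t, True):
            continue
        run = 1
        u = t - 1
        while u in cont and not o2_on.get(u, True):
            run += 1
            u -= 1
        u = t + 1
        while u in cont and not o2_on.get(u, True):
            run += 1
            u += 1
        if run >= 5:
            cands.append(clean(v))
    nadir = min(cands) if cands else None

    o2_minutes = sum(1 for t in cont if o2_on.get(t, False))
    return {
        "median_spo2": median_spo2,
        "minutes_below_level_per_hour": minutes_below,
        "nadir_spo2": nadir,
        "o2_duration_min": float(o2_minutes),
        "o2_fraction": o2_minutes / stay,
    }


def naive_quantile(values: Sequence[float], p: float) -> float:
    """Sort-and-interpolate at position 1 + p(n-1)."""
    s = sorted(values)
    h = p * (len(s) - 1)
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def naive_mann_whitney_u(g1: Sequence[float], g2: Sequence[float]) -> float:
    """U as count of pairwise wins plus half-ties for group 1."""
    u = 0.0
    for a in g1:
        for b in g2:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def naive_concordance(scores: Sequence[float], outcome: Sequence[int]) -> float:
    """All case/control pairs; ties count one half."""
    cases = [s for s, y in zip(scores, outcome) if y == 1]
    controls = [s for s, y in zip(scores, outcome) if y == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            if c > k:
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(cases) * len(controls))


def naive_greedy_match(
    scores: Dict[str, float], exposed_ids: List[str], control_ids: List[str]
) -> List[Tuple[str, str]]:
    """Greedy 1:1 matching trace, literal transcription of the rule:
    exposed in descending score order, nearest unused control by |delta|,
    ties to the lowest control index (position in control_ids)."""
    pairs = []
    available = list(control_ids)
    for eid in sorted(exposed_ids, key=lambda i: -scores[i]):
        if not available:
            break
        best, best_delta = None, None
        for cid in available:  # control_ids order = index order
            d = abs(scores[cid] - scores[eid])
            if best is None or d < best_delta:
                best, best_delta = cid, d
        pairs.append((eid, best))
        available.remove(best)
    return pairs
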