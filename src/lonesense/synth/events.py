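"""Synthetic AWARE-style phone event logs.

One simulated day yields Poisson-distributed calls (with durations),
messages, app notifications drawn from a category mix, and screen
unlock/lock pairs.  All rates scale with ``exp(sociability)`` so event
frequency is strictly monotone in the sociability input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..behavior.phone import CATEGORIES, EXAMPLE_APPS

DAY_S = 86400.0

EVENT_COLUMNS = ["participant_id", "t", "type", "duration_s", "app_package"]


@dataclass
class EventRates:
    """Base daily rates (events/day) before the sociability scaling."""

    call_incoming: float = 1.5
    call_outgoing: float = 1.8
    call_missed: float = 0.5
    call_voicemail: float = 0.25
    message_incoming: float = 12.0
    message_outgoing: float = 10.0
    notifications: float = 45.0
    unlocks: float = 30.0
    call_duration_s: float = 150.0
    screen_session_s: float = 240.0
    #: extra notifications in one highlighted category (used for couplings)
    extra_category: str | None = None
    extra_rate: float = 0.0


def default_category_mix() -> dict[str, float]:
    """A plausible notification mix over the 18 app categories."""
    w = {c: 1.0 for c in CATEGORIES}
    w.update({"Communication": 6.0, "Social": 5.0, "Entertainment": 2.5,
              "Productivity": 2.0, "Music & Audio": 1.5, "Tools": 1.5})
    tot = sum(w.values())
    return {c: v / tot for c, v in w.items()}


def _times(n: int, rng: np.random.Generator, lo_h: float = 8.0, hi_h: float = 24.0) -> np.ndarray:
    return np.sort(rng.uniform(lo_h * 3600.0, hi_h * 3600.0, size=n))


def simulate_events_day(sociability: float, category_mix: dict[str, float],
                        rng: np.random.Generator,
                        rates: EventRates | None = None,
                        participant_id: str = "p", day_offset_s: float = 0.0) -> pd.DataFrame:
    """Simulate one day of phone events; returns an EventLog-shaped frame."""
    mix_total = sum(category_mix.values())
    if category_mix and not np.isclose(mix_total, 1.0, atol=1e-6):
        raise ValueError("category_mix must sum to 1")
    unknown = set(category_mix) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown notification categories: {sorted(unknown)}")
    rates = rates or EventRates()
    mult = float(np.exp(sociability))
    rows: list[tuple] = []

    def emit(kind, t, dur=0.0, pkg=""):
        rows.append((participant_id, day_offset_s + t, kind, dur, pkg))

    for kind, base, with_dur in [("call_incoming", rates.call_incoming, True),
                                 ("call_outgoing", rates.call_outgoing, True),
                                 ("call_missed", rates.call_missed, False),
                                 ("call_voicemail", rates.call_voicemail, True)]:
        n = rng.poisson(base * mult)
        for t in _times(n, rng):
            dur = float(rng.exponential(rates.call_duration_s)) if with_dur else 0.0
            emit(kind, t, dur)
    for kind, base in [("message_incoming", rates.message_incoming),
                       ("message_outgoing", rates.message_outgoing)]:
        for t in _times(rng.poisson(base * mult), rng):
            emit(kind, t)

    cats = list(category_mix) or CATEGORIES
    probs = np.array([category_mix.get(c, 0.0) for c in cats]) if category_mix else None
    n_notif = rng.poisson(rates.notifications * mult)
    for t in _times(n_notif, rng):
        cat = cats[int(rng.choice(len(cats), p=probs))] if probs is not None else "Unknown"
        emit("notification", t, pkg=rng.choice(EXAMPLE_APPS[cat]))
    if rates.extra_category and rates.extra_rate > 0:
        for t in _times(rng.poisson(rates.extra_rate), rng):
            emit("notification", t, pkg=rng.choice(EXAMPLE_APPS[rates.extra_category]))

    # screen sessions: unlock/lock pairs, non-overlapping by construction
    n_unlock = rng.poisson(rates.unlocks * mult)
    starts = _times(n_unlock, rng)
    last_end = -1.0
    for s in starts:
        if s <= last_end:
            continue
        dur = min(float(rng.exponential(rates.screen_session_s)) + 5.0, DAY_S - s - 1.0)
        emit("screen_unlock", s)
        emit("screen_lock", s + dur)
        last_end = s + dur
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return df.sort_values("t", kind="stable").reset_index(drop=True)
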