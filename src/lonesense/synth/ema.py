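"""Latent loneliness process and EMA (momentary self-report) simulation.

Loneliness fluctuates over time: the latent state follows a standard-normal
stationary daily AR(1) plus smaller within-day variation.  Observed 0-100
scores are a bounded affine transform of the latent state with reporting
noise; prompts follow an interval-contingent schedule of five windows per
day, consecutive prompts at most four hours (plus jitter) apart.
"""

from __future__ import annotations

import numpy as np

DAY_S = 86400.0
#: prompt window centres (hours of day) for the default 5/day schedule
BASE_HOURS = (8.5, 12.0, 15.5, 19.0, 22.5)
JITTER_S = 25 * 60.0  # prompts land within +/- 25 min of the window centre


def latent_trajectory(n_days: int, ema_per_day: int, rng: np.random.Generator,
                      ar: float = 0.7, within_day_sd: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Daily AR(1) latent states plus within-day wobble.

    Returns ``(daily, per_ema)`` with shapes ``(n_days,)`` and
    ``(n_days, ema_per_day)``; the daily process is stationary with unit
    variance.
    """
    daily = np.empty(n_days)
    daily[0] = rng.normal()
    innov_sd = np.sqrt(1.0 - ar ** 2)
    for d in range(1, n_days):
        daily[d] = ar * daily[d - 1] + rng.normal(0.0, innov_sd)
    wobble = rng.normal(0.0, within_day_sd, size=(n_days, ema_per_day))
    return daily, daily[:, None] + wobble


def schedule_windows(ema_per_day: int = 5) -> list[tuple[float, float]]:
    """Prompt windows (start, end) in seconds from local midnight."""
    if ema_per_day == len(BASE_HOURS):
        centres = [h * 3600.0 for h in BASE_HOURS]
    else:
        centres = list(np.linspace(9.0, 22.0, ema_per_day) * 3600.0)
    return [(c - JITTER_S, c + JITTER_S) for c in centres]


def simulate_ema_day(latents: np.ndarray, windows: list[tuple[float, float]],
                     rng: np.random.Generator, scale: float = 20.0, offset: float = 50.0,
                     noise_sd: float = 3.0, missing_p: float = 0.0,
                     day_offset_s: float = 0.0) -> list[tuple[float, int]]:
    """One day of EMA responses: ``(t, score)`` pairs.

    ``score = clip(round(scale * latent + offset + noise), 0, 100)``; each
    response is independently missing with probability ``missing_p``.
    """
    if len(latents) != len(windows):
        raise ValueError("one latent state per schedule window required")
    rows = []
    for latent, (a, b) in zip(latents, windows):
        t = day_offset_s + rng.uniform(a, b)
        score = int(np.clip(np.round(scale * latent + offset + rng.normal(0.0, noise_sd)),
                            0, 100))
        if rng.uniform() >= missing_p:
            rows.append((t, score))
    return rows
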