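"""Cohort-level configuration for the synthetic multi-device study."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

#: feature channels whose coupling to the latent loneliness state is tunable
CHANNELS = (
    "nocturnal_hr",          # ring: nightly HR up, nightly RMSSD down
    "hrv",                   # watch: daytime HR up, IBI variability down
    "home_stay",             # phone GPS: longer home dwell
    "n_places",              # phone GPS: fewer visited places
    "communication",         # phone: fewer calls and messages
    "social_notifications",  # phone: Social-category notifications (signed)
)


@dataclass
class CohortConfig:
    """Everything the cohort generator needs; same config + seed means a
    byte-identical cohort.

    ``coupling`` maps channel names to standardized effect sizes (how many
    generator-scale units the channel moves per 1 SD of latent loneliness);
    unlisted channels default to 0.
    """

    n_participants: int = 30
    n_days: int = 56
    ema_per_day: int = 5
    ppg_fs: float = 25.0
    ppg_segment_minutes: float = 12.0
    ppg_period_hours: float = 2.0
    coupling: dict[str, float] = field(default_factory=dict)
    noise_burst_rate: float = 0.25
    seed: int = 0

    # latent / score model
    latent_ar: float = 0.7
    within_day_sd: float = 0.25
    score_scale: float = 20.0
    score_offset: float = 50.0
    score_noise_sd: float = 3.0

    # missingness (device off / uncharged, skipped prompts)
    ema_missing_p: float = 0.08
    watch_dropout_p: float = 0.08   # fraction of PPG segments lost in gaps
    ring_missing_p: float = 0.05    # fraction of nights without a summary

    #: 'waveform' simulates and processes raw PPG; 'summary' derives the
    #: watch HRV stream directly from the true beat times (fast path for
    #: modeling-level experiments)
    ppg_mode: str = "waveform"
    #: retain raw waveform segments (and noise masks) on the cohort object;
    #: disable for large cohorts, where each segment is pushed through the
    #: cleaning chain as it is generated and only its HRV row is kept
    store_ppg_segments: bool = True
    start_time_utc: str = "2021-01-11T00:00:00Z"

    def __post_init__(self):
        if self.n_participants < 1:
            raise ConfigError("n_participants", "must be >= 1")
        if self.n_days < 2:
            raise ConfigError("n_days", "must be >= 2")
        if self.ema_per_day < 1:
            raise ConfigError("ema_per_day", "must be >= 1")
        if self.ppg_fs < 20:
            raise ConfigError("ppg_fs", "must be >= 20 samples/s")
        if self.ppg_segment_minutes <= 0:
            raise ConfigError("ppg_segment_minutes", "must be positive")
        if not (0 < self.ppg_period_hours <= 24):
            raise ConfigError("ppg_period_hours", "must be in (0, 24]")
        if 24.0 % self.ppg_period_hours != 0:
            raise ConfigError("ppg_period_hours", "must divide 24")
        for k, v in self.coupling.items():
            if k not in CHANNELS:
                raise ConfigError("coupling", f"unknown channel '{k}'")
            if not np.isfinite(v):
                raise ConfigError("coupling", f"effect size for '{k}' not finite")
        for k in ("noise_burst_rate", "ema_missing_p", "watch_dropout_p", "ring_missing_p"):
            if getattr(self, k) < 0:
                raise ConfigError(k, "must be >= 0")
        if self.ppg_mode not in ("waveform", "summary"):
            raise ConfigError("ppg_mode", "must be 'waveform' or 'summary'")

    def effect(self, channel: str) -> float:
        return float(self.coupling.get(channel, 0.0))

    @property
    def segments_per_day(self) -> int:
        return int(24 // self.ppg_period_hours)


def strong_coupling_config(**overrides) -> CohortConfig:
    """The shipped strong-coupling study condition: every channel at effect
    size 1, the cohort dimensions of a 30-person, 8-week protocol."""
    base = dict(n_participants=30, n_days=56, store_ppg_segments=False,
                coupling={c: 1.0 for c in CHANNELS}, seed=20240620)
    base.update(overrides)
    return CohortConfig(**base)


def null_coupling_config(**overrides) -> CohortConfig:
    """All effect sizes zero: no stream carries label information."""
    base = dict(n_participants=12, n_days=20, store_ppg_segments=False,
                coupling={}, seed=20240620)
    base.update(overrides)
    return CohortConfig(**base)
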