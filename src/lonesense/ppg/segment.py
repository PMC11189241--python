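"""Core containers for the photoplethysmography (PPG) chain."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._compat import njit

#: quality labels used in :attr:`PPGSegment.quality`
CLEAN = 0
NOISY = 1
RECONSTRUCTED = 2


@njit(cache=False)
def _screen_ibis(ibis, lo, hi, max_rel_change):
    # range screen plus "<=30% successive change vs previous valid interval"
    valid = np.zeros(len(ibis), dtype=np.bool_)
    prev = -1.0
    for i in range(len(ibis)):
        ibi = ibis[i]
        ok = lo <= ibi <= hi
        if ok and prev > 0:
            ok = abs(ibi - prev) <= max_rel_change * prev
        valid[i] = ok
        if ok:
            prev = ibi
    return valid


@dataclass
class PPGSegment:
    """One contiguous PPG recording (the watch records 12 min every 2 h).

    Parameters
    ----------
    participant_id:
        Identifier of the wearer.
    start_time:
        Segment start, in seconds since the cohort reference epoch.
    fs:
        Sampling rate in samples/s.
    samples:
        Raw optical samples (arbitrary units).
    quality:
        Per analysis-window label (``CLEAN``/``NOISY``/``RECONSTRUCTED``),
        filled in by the signal-quality assessment; ``None`` until then.
    quality_window_s:
        Length in seconds of each analysis window of ``quality``.
    """

    participant_id: str
    start_time: float
    fs: float
    samples: np.ndarray
    quality: np.ndarray | None = None
    quality_window_s: float = 5.0
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def n_quality_windows(self) -> int:
        return int(np.ceil(self.duration_s / self.quality_window_s))

    def analyzable_mask(self) -> np.ndarray:
        """Boolean per-sample mask of clean or reconstructed regions."""
        if self.quality is None:
            return np.ones(len(self.samples), dtype=bool)
        win = (np.arange(len(self.samples)) / self.fs // self.quality_window_s).astype(int)
        win = np.minimum(win, len(self.quality) - 1)
        return self.quality[win] != NOISY


@dataclass
class IBISeries:
    """Inter-beat intervals derived from detected systolic peaks.

    ``ibis[i]`` is ``1000 * (beat_times[i+1] - beat_times[i])`` in ms and
    ``valid[i]`` marks intervals that survive physiological screening
    (300-2000 ms, successive change <= 30 %).
    """

    beat_times: np.ndarray
    ibis: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.ibis = np.asarray(self.ibis, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.beat_times) and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if len(self.ibis) != max(0, len(self.beat_times) - 1):
            raise ValueError("ibis must have len(beat_times) - 1 entries")
        if len(self.valid) != len(self.ibis):
            raise ValueError("valid must align with ibis")

    @classmethod
    def from_beats(cls, beat_times: np.ndarray,
                   ibi_range_ms: tuple[float, float] = (300.0, 2000.0),
                   max_rel_change: float = 0.30) -> "IBISeries":
        """Build the series and apply the physiological validity screen."""
        beat_times = np.asarray(beat_times, dtype=float)
        if len(beat_times) < 2:
            return cls(beat_times, np.empty(0), np.empty(0, dtype=bool))
        ibis = np.diff(beat_times) * 1000.0
        lo, hi = ibi_range_ms
        valid = _screen_ibis(ibis, lo, hi, max_rel_change)
        return cls(beat_times, ibis, valid)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_nn(self) -> np.ndarray:
        """Valid normal-to-normal intervals, ms."""
        return self.ibis[self.valid]
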