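"""Synthetic wrist-PPG waveforms with known beat times and noise masks.

The pulse model is deliberately simple: each heart beat contributes a systolic
Gaussian bump plus a smaller, delayed dicrotic bump, on top of a slow low
amplitude baseline.  Motion-artifact bursts are additive large-amplitude
baseline wander (0.1-0.5 Hz) plus broadband white noise; burst durations are
drawn from a mixture that straddles the 15-s reconstruction threshold so both
the "reconstruct" and the "discard" paths of the cleaning pipeline get
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class NoiseSpec:
    """Motion-artifact burst model for one segment.

    ``burst_rate`` is the expected number of bursts per segment; duration is a
    mixture of short (< 15 s, reconstructable) and long (>= 15 s, discarded)
    bursts.
    """

    burst_rate: float = 0.0
    short_frac: float = 0.6
    short_range_s: tuple[float, float] = (4.0, 12.0)
    long_range_s: tuple[float, float] = (18.0, 45.0)
    wander_freq_hz: tuple[float, float] = (0.1, 0.5)
    wander_amp: tuple[float, float] = (3.0, 8.0)
    white_sd: tuple[float, float] = (0.6, 1.5)


def _pulse_train(beat_times: np.ndarray, ibis_s: np.ndarray, n: int, fs: float) -> np.ndarray:
    """Sum of two Gaussians per beat, fully vectorised over beats."""
    sig = np.zeros(n)
    if len(beat_times) == 0:
        return sig
    # systolic peak at the beat time, dicrotic bump ~35% of the local IBI later
    ibi_of_beat = np.concatenate([ibis_s, ibis_s[-1:]]) if len(ibis_s) else np.full(1, 1.0)
    centers = np.concatenate([beat_times, beat_times + 0.35 * ibi_of_beat])
    sigmas = np.concatenate([0.09 * ibi_of_beat, 0.14 * ibi_of_beat])
    amps = np.concatenate([np.ones(len(beat_times)), 0.35 * np.ones(len(beat_times))])

    wmax = int(np.ceil(4.0 * sigmas.max() * fs))
    offs = np.arange(-wmax, wmax + 1)
    cidx = np.round(centers * fs).astype(int)
    pos = cidx[:, None] + offs[None, :]
    tt = pos / fs
    vals = amps[:, None] * np.exp(-0.5 * ((tt - centers[:, None]) / sigmas[:, None]) ** 2)
    ok = (pos >= 0) & (pos < n)
    np.add.at(sig, pos[ok], vals[ok])
    return sig


def simulate_beats(mean_hr: float, hrv_sd_ms: float, duration_s: float,
                   rng: np.random.Generator) -> np.ndarray:
    """True systolic beat times (s) with Gaussian beat-to-beat jitter.

    IBIs are ``60/mean_hr + N(0, hrv_sd_ms)`` clipped to the physiological
    [0.3, 2.0] s range.
    """
    if not 30.0 <= mean_hr <= 220.0:
        raise ValueError("mean_hr must be within [30, 220] bpm")
    mean_ibi = 60.0 / mean_hr
    if duration_s < 2 * mean_ibi:
        raise ValueError("segment too short to contain two beats")
    n_draw = int(duration_s / mean_ibi) + 10
    ibis = mean_ibi + rng.normal(0.0, hrv_sd_ms / 1000.0, size=n_draw)
    ibis = np.clip(ibis, 0.3, 2.0)
    t0 = rng.uniform(0.2, 0.2 + mean_ibi)
    beat_times = t0 + np.concatenate([[0.0], np.cumsum(ibis)])
    return beat_times[beat_times < duration_s - 0.1]


def simulate_ppg_segment(mean_hr: float, hrv_sd_ms: float, duration_s: float, fs: float,
                         noise_spec: NoiseSpec | None = None,
                         rng: np.random.Generator | None = None):
    """Simulate one PPG segment.

    Parameters
    ----------
    mean_hr:
        Mean heart rate in beats/min (30-220).
    hrv_sd_ms:
        Standard deviation of the beat-to-beat interval jitter, ms.
    duration_s, fs:
        Segment duration (s) and sampling rate (samples/s).
    noise_spec:
        Burst-noise model; ``None`` or rate 0 gives a clean segment.
    rng:
        numpy Generator; a fresh default Generator is used if omitted.

    Returns
    -------
    samples : ndarray
        The simulated optical signal.
    beat_times : ndarray
        True systolic peak times in seconds from segment start.
    noise_mask : ndarray of bool
        Per-sample mask of the injected noise bursts.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng() if rng is None else rng
    beat_times = simulate_beats(mean_hr, hrv_sd_ms, duration_s, rng)
    ibis = np.diff(beat_times)

    n = int(round(duration_s * fs))
    sig = _pulse_train(beat_times, ibis, n, fs)
    # slow respiratory-like baseline, small relative to the pulse
    t = np.arange(n) / fs
    sig += 0.08 * np.sin(2 * np.pi * rng.uniform(0.15, 0.3) * t + rng.uniform(0, 2 * np.pi))

    noise_mask = np.zeros(n, dtype=bool)
    if noise_spec is not None and noise_spec.burst_rate > 0:
        n_bursts = rng.poisson(noise_spec.burst_rate)
        for _ in range(n_bursts):
            if rng.uniform() < noise_spec.short_frac:
                dur = rng.uniform(*noise_spec.short_range_s)
            else:
                dur = rng.uniform(*noise_spec.long_range_s)
            dur = min(dur, duration_s)
            start = rng.uniform(0.0, duration_s - dur)
            i0, i1 = int(start * fs), int((start + dur) * fs)
            tb = t[i0:i1]
            wander = rng.uniform(*noise_spec.wander_amp) * np.sin(
                2 * np.pi * rng.uniform(*noise_spec.wander_freq_hz) * tb + rng.uniform(0, 2 * np.pi))
            white = rng.normal(0.0, rng.uniform(*noise_spec.white_sd), size=i1 - i0)
            sig[i0:i1] += wander + white
            noise_mask[i0:i1] = True

    return sig, beat_times, noise_mask
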