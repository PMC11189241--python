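"""Shipped synthetic benchmarks for calibrating and scoring the PPG chain."""

from __future__ import annotations

import numpy as np

from ..ppg.segment import PPGSegment
from .ppg import NoiseSpec, simulate_ppg_segment

BENCHMARK_SEED = 20240620


def sqa_benchmark(seed: int = BENCHMARK_SEED, n_windows: int = 400,
                  fs: float = 25.0, window_s: float = 5.0,
                  segment_s: float = 60.0):
    """Labelled clean/noisy analysis windows for SQA calibration and scoring.

    Simulates 60-s segments with frequent motion bursts and labels each
    ``window_s`` window noisy when more than half of its samples fall inside
    an injected burst.  Returns ``(segments, labels)`` where ``labels[i]``
    aligns with the quality windows of ``segments[i]``.
    """
    rng = np.random.default_rng(seed)
    spec = NoiseSpec(burst_rate=1.2)
    segments, labels = [], []
    total = 0
    wlen = int(window_s * fs)
    while total < n_windows:
        hr = rng.uniform(55.0, 95.0)
        sd = rng.uniform(20.0, 60.0)
        sig, beats, mask = simulate_ppg_segment(hr, sd, segment_s, fs, spec, rng)
        seg = PPGSegment("bench", 0.0, fs, sig, quality_window_s=window_s)
        n_win = seg.n_quality_windows
        lab = np.empty(n_win, dtype=bool)
        for w in range(n_win):
            frac = mask[w * wlen:(w + 1) * wlen].mean()
            lab[w] = frac > 0.5
        segments.append(seg)
        labels.append(lab)
        total += n_win
    return segments, labels
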