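"""Deterministic reconstruction of short noisy runs inside a PPG segment.

Stand-in for a learned waveform reconstructor: noisy runs shorter than 15 s
that are bounded by clean windows on both sides are replaced by tiling a
heart-cycle template (built from the neighbouring clean cycles) at the local
inter-beat interval.  The tiles are phase-locked to the clean anchor beats
on both sides of the run, carry deterministic pseudo-random beat-to-beat
jitter matched to the local IBI spread (so segment-level variability
statistics are not deflated by the insertion), are amplitude matched by
construction, and cross-fade linearly into the surrounding signal.  Runs of
15 s or more, and runs touching a segment edge, are left noisy and excluded
downstream.
"""

from __future__ import annotations

import numpy as np

from .peaks import filtered_and_peaks
from .segment import CLEAN, NOISY, PPGSegment, RECONSTRUCTED

MAX_RECONSTRUCT_S = 15.0
_CROSSFADE_S = 0.2
_NEIGHBOR_CYCLES = 8


def _noisy_runs(quality: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) window-index runs of noisy labels, stop exclusive."""
    runs = []
    in_run = False
    for i, q in enumerate(quality):
        if q == NOISY and not in_run:
            start, in_run = i, True
        elif q != NOISY and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(quality)))
    return runs


def reconstruct_segment(segment: PPGSegment,
                        max_reconstruct_s: float = MAX_RECONSTRUCT_S) -> PPGSegment:
    """Reconstruct eligible noisy runs; returns a new segment object.

    Requires the quality mask (see :func:`lonesense.ppg.sqa.apply_sqa`).
    A fully noisy segment is returned unchanged apart from a flag.
    """
    if segment.quality is None:
        raise ValueError("quality mask not computed; run SQA first")
    quality = segment.quality.copy()
    samples = segment.samples.copy()
    fs = segment.fs
    win = segment.quality_window_s
    wlen = int(round(win * fs))
    runs = _noisy_runs(quality)
    provenance: list[dict] = []

    if not (quality != NOISY).any():
        out = PPGSegment(segment.participant_id, segment.start_time, fs, samples,
                         quality, win, dict(segment.flags))
        out.flags["all_noisy"] = True
        return out

    filtered, peaks = filtered_and_peaks(segment)
    win_of_peak = np.minimum((peaks // wlen), len(quality) - 1)
    clean_peaks = peaks[quality[win_of_peak] == CLEAN]

    for start, stop in runs:
        run_s = (stop - start) * win
        at_edge = start == 0 or stop == len(quality)
        if run_s >= max_reconstruct_s or at_edge:
            provenance.append({"windows": (start, stop), "action": "discard"})
            continue
        i0, i1 = start * wlen, min(stop * wlen, len(samples))
        # anchor half an analysis window away from the run: burst edges can
        # leak a little noise into the adjacent clean-labelled windows
        margin = wlen // 2
        before = clean_peaks[clean_peaks < i0 - margin][-_NEIGHBOR_CYCLES - 1:]
        after = clean_peaks[clean_peaks >= i1 + margin][:_NEIGHBOR_CYCLES + 1]
        ibis = np.concatenate([np.diff(before), np.diff(after)])
        ibis = ibis[(ibis > 0.3 * fs) & (ibis < 2.0 * fs)]
        if len(ibis) < 2 or len(before) < 2 or len(after) < 1:
            provenance.append({"windows": (start, stop), "action": "discard"})
            continue
        local_ibi = int(round(np.median(ibis)))

        # template: mean of neighbouring clean cycles resampled to local_ibi
        bounds = np.concatenate([before, after])
        cycles = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            if 0.3 * fs < b - a < 2.0 * fs:
                src = samples[a:b]
                pos = np.linspace(0, len(src) - 1, local_ibi)
                cycles.append(np.interp(pos, np.arange(len(src)), src))
        if not cycles:
            provenance.append({"windows": (start, stop), "action": "discard"})
            continue
        template = np.mean(cycles, axis=0)

        # tile from the last clean peak before the run to the first clean
        # peak after it.  The synthetic beats are phase-locked to BOTH anchor
        # peaks (no spurious junction IBI) and carry pseudo-random
        # beat-to-beat jitter matched to the neighbourhood's IBI spread, so
        # the insertion does not deflate the segment's variability
        # statistics.  The jitter is seeded from the run position: the
        # reconstruction stays a deterministic function of the segment.
        left = int(before[-1])
        right = int(after[0])
        k = max(int(round((right - left) / local_ibi)), 1)
        period = (right - left) / k
        sigma = float(np.std(ibis))
        jrng = np.random.default_rng(abs(hash((start, stop, left, right))) % (2 ** 31))
        d = jrng.normal(0.0, sigma, size=k)
        d -= d.mean()  # bridge: synthetic beats still end exactly on `right`
        bounds_syn = np.concatenate([[left], left + np.cumsum(period + d)])
        bounds_syn = np.round(bounds_syn).astype(int)
        bounds_syn[-1] = right
        synth = np.empty(right - left)
        for a2, b2 in zip(bounds_syn[:-1], bounds_syn[1:]):
            if b2 <= a2:
                continue
            pos = np.linspace(0.0, len(template) - 1.0, b2 - a2, endpoint=False)
            lo_t = np.floor(pos).astype(int)
            wt = pos - lo_t
            synth[a2 - left:b2 - left] = template[lo_t] * (1.0 - wt) + \
                template[np.minimum(lo_t + 1, len(template) - 1)] * wt

        # short linear crossfade into the untouched signal at both ends
        nf = min(max(int(_CROSSFADE_S * fs), 1), len(synth) // 2)
        ramp = np.linspace(0.0, 1.0, nf)
        synth[:nf] = ramp * synth[:nf] + (1 - ramp) * samples[left:left + nf]
        synth[-nf:] = ramp[::-1] * synth[-nf:] + (1 - ramp[::-1]) * samples[right - nf:right]
        samples[left:right] = synth
        quality[start:stop] = RECONSTRUCTED
        provenance.append({"windows": (start, stop), "action": "reconstructed",
                           "local_ibi_ms": 1000.0 * local_ibi / fs})

    out = PPGSegment(segment.participant_id, segment.start_time, fs, samples,
                     quality, win, dict(segment.flags))
    out.flags["reconstruction"] = provenance
    return out
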