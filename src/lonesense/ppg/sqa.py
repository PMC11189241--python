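"""Signal-quality assessment (SQA): label analysis windows clean or noisy.

Five features are extracted per analysis window: interquartile range,
standard deviation of the power spectral density, range of per-cycle energy,
mean Euclidean distance between length-normalised heart cycles and their
template, and mean correlation between cycles and the template (the template
is the pointwise mean of the length-normalised cycles).  A window is noisy
when a majority of features cross their thresholds in the noise direction
(an any-crossing variant is available); thresholds ship pre-calibrated on the
package's synthetic clean/noisy benchmark and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .peaks import adaptive_peak_indices, bandpass
from .segment import CLEAN, NOISY, PPGSegment

CYCLE_RESAMPLE_N = 40


@dataclass(frozen=True)
class SQAFeatures:
    iqr: float
    sd_psd: float
    cycle_energy_range: float
    mean_euclid_dist: float
    mean_template_corr: float
    degenerate: bool = False  # fewer than 2 detectable heart cycles


@dataclass(frozen=True)
class SQAThresholds:
    """Noise direction: larger iqr/sd_psd/energy-range/distance, smaller corr.

    Defaults were calibrated once, with :func:`calibrate_thresholds`, on a
    2,400-window synthetic calibration set drawn from the same generator as
    the shipped benchmark (see
    :func:`lonesense.synth.benchmark.sqa_benchmark`).
    """

    iqr_max: float = 1.22
    sd_psd_max: float = 1.54
    cycle_energy_range_max: float = 114.7
    euclid_max: float = 0.340
    corr_min: float = 0.785


DEFAULT_THRESHOLDS = SQAThresholds()


def _resample_cycles(filtered: np.ndarray, bounds: np.ndarray, n_out: int) -> np.ndarray:
    """Length-normalise cycles (between consecutive peak indices) by linear
    interpolation at fractional sample positions; fully vectorised."""
    starts = bounds[:-1].astype(float)
    lens = np.diff(bounds).astype(float)
    frac = np.linspace(0.0, 1.0, n_out)
    pos = starts[:, None] + lens[:, None] * frac[None, :]
    lo = np.floor(pos).astype(int)
    lo = np.clip(lo, 0, len(filtered) - 2)
    w = pos - lo
    return filtered[lo] * (1.0 - w) + filtered[lo + 1] * w


def compute_sqa_features(window: np.ndarray, fs: float,
                         filtered: np.ndarray | None = None,
                         peak_idx: np.ndarray | None = None) -> SQAFeatures:
    """The five SQA features for one analysis window.

    ``filtered``/``peak_idx`` allow a caller that already band-passed the
    parent segment to reuse its work (indices relative to ``window``);
    otherwise the window is filtered and peaks detected standalone.
    """
    window = np.asarray(window, dtype=float)
    iqr = float(np.subtract(*np.percentile(window, [75, 25])))
    if len(window) >= 8:
        _, pxx = _signal.periodogram(window, fs=fs, detrend="constant")
        sd_psd = float(np.std(pxx))
    else:
        sd_psd = 0.0

    if filtered is None:
        filtered = bandpass(window, fs) if len(window) > 21 else window - window.mean()
    if peak_idx is None:
        peak_idx = adaptive_peak_indices(filtered, fs)
    if len(peak_idx) < 3:  # fewer than 2 complete cycles
        return SQAFeatures(iqr, sd_psd, 0.0, 0.0, 0.0, degenerate=True)

    centered = window - window.mean()
    cum = np.concatenate([[0.0], np.cumsum(centered ** 2)])
    energies = cum[peak_idx[1:]] - cum[peak_idx[:-1]]
    energy_range = float(energies.max() - energies.min())

    cyc = _resample_cycles(filtered, peak_idx, CYCLE_RESAMPLE_N)
    template = cyc.mean(axis=0)
    diff = cyc - template
    mean_euclid = float(np.sqrt((diff ** 2).mean(axis=1)).mean())
    ct = template - template.mean()
    cc = cyc - cyc.mean(axis=1, keepdims=True)
    denom = np.sqrt((cc ** 2).sum(axis=1) * (ct ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corrs = np.where(denom > 1e-12, (cc * ct).sum(axis=1) / denom, 0.0)
    return SQAFeatures(iqr, sd_psd, energy_range, mean_euclid, float(corrs.mean()))


def classify_quality(features: SQAFeatures,
                     thresholds: SQAThresholds = DEFAULT_THRESHOLDS,
                     rule: str = "majority") -> str:
    """``"clean"`` or ``"noisy"``; crossings are strict inequalities."""
    if features.degenerate:
        return "noisy"
    crossings = [features.iqr > thresholds.iqr_max,
                 features.sd_psd > thresholds.sd_psd_max,
                 features.cycle_energy_range > thresholds.cycle_energy_range_max,
                 features.mean_euclid_dist > thresholds.euclid_max,
                 features.mean_template_corr < thresholds.corr_min]
    if rule == "any":
        noisy = any(crossings)
    elif rule == "majority":
        noisy = sum(crossings) >= 3
    else:
        raise ValueError(f"unknown SQA rule {rule!r}")
    return "noisy" if noisy else "clean"


def segment_sqa_features(segment: PPGSegment, window_s: float = 5.0) -> list[SQAFeatures]:
    """SQA features for every analysis window of a segment, batched.

    Filters and peak-detects the segment once and evaluates all windows with
    vectorised array operations; numerically equivalent to calling
    :func:`compute_sqa_features` per window with the shared peak set.
    """
    from .peaks import filtered_and_peaks

    fs = segment.fs
    x = segment.samples
    wlen = int(round(window_s * fs))
    n = len(x)
    n_full = n // wlen
    n_win = int(np.ceil(n / wlen))
    filtered, peaks = filtered_and_peaks(segment)

    W = x[:n_full * wlen].reshape(n_full, wlen)
    q75, q25 = np.percentile(W, [75, 25], axis=1)
    iqr = q75 - q25
    if wlen >= 8:
        _, pxx = _signal.periodogram(W, fs=fs, detrend="constant", axis=-1)
        sd_psd = np.std(pxx, axis=1)
    else:
        sd_psd = np.zeros(n_full)
    win_mean = W.mean(axis=1)

    # cycles whose bounding peaks fall in the same window
    pk_w = peaks // wlen
    same = (pk_w[:-1] == pk_w[1:]) & (pk_w[:-1] < n_full) if len(peaks) > 1 else np.empty(0, bool)
    a = peaks[:-1][same]
    b = peaks[1:][same]
    cw = pk_w[:-1][same]
    n_pk_win = np.bincount(pk_w[peaks < n_full * wlen], minlength=n_full) if len(peaks) else np.zeros(n_full, int)

    feats: list[SQAFeatures] = [None] * n_win  # type: ignore[list-item]
    degenerate = n_pk_win < 3
    if len(a):
        s1 = np.concatenate([[0.0], np.cumsum(x)])
        s2 = np.concatenate([[0.0], np.cumsum(x ** 2)])
        m = win_mean[cw]
        energy = (s2[b] - s2[a]) - 2 * m * (s1[b] - s1[a]) + m ** 2 * (b - a)

        frac = np.linspace(0.0, 1.0, CYCLE_RESAMPLE_N)
        pos = a[:, None] + (b - a)[:, None].astype(float) * frac[None, :]
        lo = np.floor(pos).astype(int)
        lo = np.minimum(lo, (cw * wlen + wlen - 2)[:, None])
        wt = pos - lo
        cyc = filtered[lo] * (1.0 - wt) + filtered[lo + 1] * wt

        # group by window (cycles are already window-sorted)
        starts = np.searchsorted(cw, np.arange(n_full))
        counts = np.diff(np.concatenate([starts, [len(cw)]]))
        has = counts > 0
        idx = np.minimum(starts, max(len(cw) - 1, 0))
        tmpl_sum = np.add.reduceat(cyc, idx, axis=0)
        tmpl = np.where(has[:, None], tmpl_sum / np.maximum(counts, 1)[:, None], 0.0)

        diff = cyc - tmpl[cw]
        euclid_c = np.sqrt((diff ** 2).mean(axis=1))
        ct = tmpl - tmpl.mean(axis=1, keepdims=True)
        cc = cyc - cyc.mean(axis=1, keepdims=True)
        den = np.sqrt((cc ** 2).sum(axis=1) * (ct[cw] ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr_c = np.where(den > 1e-12, (cc * ct[cw]).sum(axis=1) / den, 0.0)

        def wmean(v):
            out = np.add.reduceat(v, idx)
            return np.where(has, out / np.maximum(counts, 1), 0.0)

        e_rng = np.zeros(n_full)
        if len(energy):
            e_max = np.maximum.reduceat(energy, idx)
            e_min = np.minimum.reduceat(energy, idx)
            e_rng = np.where(has, e_max - e_min, 0.0)
        euclid_w = wmean(euclid_c)
        corr_w = wmean(corr_c)
    else:
        e_rng = np.zeros(n_full)
        euclid_w = np.zeros(n_full)
        corr_w = np.zeros(n_full)

    for w in range(n_full):
        if degenerate[w]:
            feats[w] = SQAFeatures(float(iqr[w]), float(sd_psd[w]), 0.0, 0.0, 0.0, True)
        else:
            feats[w] = SQAFeatures(float(iqr[w]), float(sd_psd[w]), float(e_rng[w]),
                                   float(euclid_w[w]), float(corr_w[w]))
    for w in range(n_full, n_win):  # trailing partial window, rare
        i0 = w * wlen
        pk = peaks[(peaks >= i0) & (peaks < n)] - i0
        feats[w] = compute_sqa_features(x[i0:], fs, filtered=filtered[i0:], peak_idx=pk)
    return feats


def quality_mask(segment: PPGSegment, thresholds: SQAThresholds = DEFAULT_THRESHOLDS,
                 window_s: float = 5.0, rule: str = "majority") -> np.ndarray:
    """Per-window clean/noisy labels for a whole segment."""
    feats = segment_sqa_features(segment, window_s)
    labels = np.empty(len(feats), dtype=np.int8)
    for w, f in enumerate(feats):
        labels[w] = NOISY if classify_quality(f, thresholds, rule) == "noisy" else CLEAN
    return labels


def apply_sqa(segment: PPGSegment, thresholds: SQAThresholds = DEFAULT_THRESHOLDS,
              window_s: float = 5.0, rule: str = "majority") -> PPGSegment:
    """Return the segment with its quality mask filled in."""
    segment.quality = quality_mask(segment, thresholds, window_s, rule)
    segment.quality_window_s = window_s
    return segment


def calibrate_thresholds(features: list[SQAFeatures], labels: np.ndarray,
                         n_grid: int = 197) -> SQAThresholds:
    """Derive per-feature thresholds from a labelled benchmark.

    Each feature's threshold is chosen independently to minimise that
    feature's single-feature classification error over a quantile grid of
    candidate cut points (strictly greater crosses for the four upward
    features, strictly smaller for the template correlation).
    """
    labels = np.asarray(labels, dtype=bool)

    def best_cut(vals, direction_up: bool) -> float:
        cand = np.unique(np.quantile(vals, np.linspace(0.01, 0.99, n_grid)))
        pred = (vals[None, :] > cand[:, None]) if direction_up else (vals[None, :] < cand[:, None])
        errs = (pred != labels[None, :]).mean(axis=1)
        return float(cand[int(np.argmin(errs))])

    arr = {k: np.array([getattr(f, k) for f in features]) for k in
           ("iqr", "sd_psd", "cycle_energy_range", "mean_euclid_dist", "mean_template_corr")}
    return SQAThresholds(
        iqr_max=best_cut(arr["iqr"], True),
        sd_psd_max=best_cut(arr["sd_psd"], True),
        cycle_energy_range_max=best_cut(arr["cycle_energy_range"], True),
        euclid_max=best_cut(arr["mean_euclid_dist"], True),
        corr_min=best_cut(arr["mean_template_corr"], False),
    )
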