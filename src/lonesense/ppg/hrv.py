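"""Heart-rate and heart-rate-variability features from an IBI series.

Time-domain features use the population (ddof 0) standard deviation
convention throughout.  Spectral features come from a 4-Hz linearly
interpolated NN series (linear detrend, Hann-window Welch with 120-s
segments and 50 % overlap) integrated over LF [0.04, 0.15) Hz and
HF [0.15, 0.4) Hz, in ms^2.  SDANN1/SDANN5 are the standard deviations of
per-1-min / per-5-min mean NN intervals across complete bins; on a 12-min
recording SDANN5 rests on only two complete bins and is flagged
low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from scipy import signal as _signal

from .segment import IBISeries

MIN_VALID_IBIS = 10
MIN_SPECTRAL_SPAN_S = 120.0
INTERP_HZ = 4.0
WELCH_SEG_S = 120.0
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

HRV_FEATURES = ["mean_nn", "hr", "sdnn", "rmssd", "cvsd", "cvnn",
                "lf", "hf", "lfn", "hfn", "sdann1", "sdann5"]


@dataclass
class HRVFeatures:
    mean_nn: float = np.nan   # ms
    hr: float = np.nan        # beats/min, 60000/mean_nn
    sdnn: float = np.nan      # ms, population SD of NN
    rmssd: float = np.nan     # ms, RMS of successive NN differences
    cvsd: float = np.nan      # rmssd / mean_nn
    cvnn: float = np.nan      # sdnn / mean_nn
    lf: float = np.nan        # ms^2
    hf: float = np.nan        # ms^2
    lfn: float = np.nan       # lf / (lf + hf)
    hfn: float = np.nan       # hf / (lf + hf)
    sdann1: float = np.nan    # ms
    sdann5: float = np.nan    # ms
    n_valid_ibis: int = 0
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "flags"}


def _band_power(freqs: np.ndarray, pxx: np.ndarray, band: tuple[float, float]) -> float:
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 0.0
    m = (freqs >= band[0]) & (freqs < band[1])
    return float(pxx[m].sum() * df)


def _sdann(nn_ms: np.ndarray, nn_t: np.ndarray, duration_s: float, bin_s: float) -> float:
    n_bins = int(duration_s // bin_s)
    if n_bins < 2:
        return np.nan
    which = (nn_t // bin_s).astype(int)
    ok = which < n_bins
    which, vals = which[ok], nn_ms[ok]
    means = []
    for b in range(n_bins):
        v = vals[which == b]
        if len(v):
            means.append(v.mean())
    if len(means) < 2:
        return np.nan
    return float(np.std(means))


def compute_hrv_features(ibi: IBISeries, segment_duration_s: float) -> HRVFeatures:
    """All HR/HRV features for one recording.

    Requires >= 10 valid IBIs for the time-domain block and >= 2 min of valid
    beat span for the spectral block; unfulfilled blocks are NaN-marked with
    a reason in ``flags``.
    """
    out = HRVFeatures()
    nn = ibi.valid_nn()
    out.n_valid_ibis = len(nn)
    if len(nn) < MIN_VALID_IBIS:
        out.flags["reason"] = f"only {len(nn)} valid IBIs (< {MIN_VALID_IBIS})"
        return out

    out.mean_nn = float(nn.mean())
    out.hr = 60000.0 / out.mean_nn
    out.sdnn = float(np.std(nn))
    succ = np.flatnonzero(ibi.valid[1:] & ibi.valid[:-1])
    if len(succ):
        d = ibi.ibis[succ + 1] - ibi.ibis[succ]
        out.rmssd = float(np.sqrt(np.mean(d ** 2)))
        out.cvsd = out.rmssd / out.mean_nn
    out.cvnn = out.sdnn / out.mean_nn

    nn_t = ibi.beat_times[1:][ibi.valid]  # time of each NN interval's end beat
    t_rel = nn_t - ibi.beat_times[0]
    out.sdann1 = float(_sdann(nn, t_rel, segment_duration_s, 60.0))
    out.sdann5 = float(_sdann(nn, t_rel, segment_duration_s, 300.0))
    if segment_duration_s < 3 * 300.0 and np.isfinite(out.sdann5):
        out.flags["sdann5_low_confidence"] = True

    span = nn_t[-1] - nn_t[0] if len(nn_t) > 1 else 0.0
    if span < MIN_SPECTRAL_SPAN_S:
        out.flags["spectral"] = f"valid span {span:.0f}s < {MIN_SPECTRAL_SPAN_S:.0f}s"
        return out
    ts = np.arange(nn_t[0], nn_t[-1], 1.0 / INTERP_HZ)
    x = np.interp(ts, nn_t, nn)
    nper = min(int(WELCH_SEG_S * INTERP_HZ), len(x))
    freqs, pxx = _signal.welch(x, fs=INTERP_HZ, window="hann", nperseg=nper,
                               noverlap=nper // 2, detrend="linear")
    out.lf = _band_power(freqs, pxx, LF_BAND)
    out.hf = _band_power(freqs, pxx, HF_BAND)
    tot = out.lf + out.hf
    if tot > 0:
        out.lfn = out.lf / tot
        out.hfn = out.hf / tot
    return out
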