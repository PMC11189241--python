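"""PPG chain: SQA features, reconstruction contract, peak detection, HRV."""

import numpy as np
import pytest

from lonesense.ppg import (CLEAN, IBISeries, NOISY, PPGSegment, RECONSTRUCTED,
                           apply_sqa, classify_quality, compute_hrv_features,
                           compute_sqa_features, detect_systolic_peaks,
                           quality_mask, reconstruct_segment)
from lonesense.ppg.hrv import HF_BAND, INTERP_HZ, LF_BAND, WELCH_SEG_S
from lonesense.ppg.sqa import DEFAULT_THRESHOLDS, SQAFeatures, segment_sqa_features
from lonesense.synth import NoiseSpec, simulate_ppg_segment

FS = 25.0


def _clean_segment(rng, hr=75, sd=40, dur=720):
    sig, beats, _ = simulate_ppg_segment(hr, sd, dur, FS, None, rng)
    return PPGSegment("p", 0.0, FS, sig), beats


# ---------------------------------------------------------------------------
# SQA

class TestSQAFeatures:
    def test_constant_signal_zero_variance_features(self):
        f = compute_sqa_features(np.full(125, 3.0), FS)
        assert f.iqr == 0.0
        assert f.sd_psd == pytest.approx(0.0, abs=1e-12)
        assert f.degenerate and f.mean_template_corr == 0.0

    def test_clean_pulse_train_high_template_corr(self, rng):
        seg, _ = _clean_segment(rng, sd=0)
        feats = segment_sqa_features(seg)
        corr = [f.mean_template_corr for f in feats if not f.degenerate]
        assert np.median(corr) >= 0.99

    def test_noise_increases_iqr_and_energy_range(self, rng):
        sig, beats, _ = simulate_ppg_segment(70, 20, 60, FS, None, rng)
        burst = np.zeros_like(sig)
        t = np.arange(len(sig)) / FS
        burst[250:750] = 5.0 * np.sin(2 * np.pi * 0.3 * t[250:750]) + \
            rng.normal(0, 1.0, 500)
        f_clean = compute_sqa_features(sig[250:750], FS)
        f_noisy = compute_sqa_features((sig + burst)[250:750], FS)
        assert f_noisy.iqr > f_clean.iqr
        assert f_noisy.cycle_energy_range > f_clean.cycle_energy_range

    def test_batch_equals_per_window(self, rng):
        from lonesense.ppg.peaks import filtered_and_peaks

        sig, _, _ = simulate_ppg_segment(70, 40, 120, FS, NoiseSpec(burst_rate=1.0), rng)
        seg = PPGSegment("p", 0.0, FS, sig)
        batch = segment_sqa_features(seg)
        filtered, peaks = filtered_and_peaks(seg)
        wlen = int(5 * FS)
        for w, fb in enumerate(batch):
            i0, i1 = w * wlen, min((w + 1) * wlen, len(sig))
            pk = peaks[(peaks >= i0) & (peaks < i1)] - i0
            fw = compute_sqa_features(sig[i0:i1], FS, filtered=filtered[i0:i1], peak_idx=pk)
            for k in ("iqr", "sd_psd", "cycle_energy_range",
                      "mean_euclid_dist", "mean_template_corr"):
                assert getattr(fb, k) == pytest.approx(getattr(fw, k), abs=1e-8)


class TestClassifyQuality:
    def test_degenerate_is_noisy(self):
        f = SQAFeatures(0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
        assert classify_quality(f) == "noisy"

    def test_features_exactly_at_thresholds_are_clean(self):
        t = DEFAULT_THRESHOLDS
        f = SQAFeatures(t.iqr_max, t.sd_psd_max, t.cycle_energy_range_max,
                        t.euclid_max, t.corr_min)
        assert classify_quality(f, rule="any") == "clean"
        assert classify_quality(f, rule="majority") == "clean"

    def test_any_rule_stricter_than_majority(self):
        t = DEFAULT_THRESHOLDS
        one_crossing = SQAFeatures(t.iqr_max * 2, 0.0, 0.0, 0.0, 1.0)
        assert classify_quality(one_crossing, rule="any") == "noisy"
        assert classify_quality(one_crossing, rule="majority") == "clean"


# ---------------------------------------------------------------------------
# reconstruction

def _burst_segment(rng, burst_start_s, burst_dur_s, dur=720.0, hr=72, sd=30):
    """A segment with one exactly-placed wander+white noise burst."""
    sig, beats, _ = simulate_ppg_segment(hr, sd, dur, FS, None, rng)
    i0, i1 = int(burst_start_s * FS), int((burst_start_s + burst_dur_s) * FS)
    t = np.arange(len(sig)) / FS
    sig = sig.copy()
    sig[i0:i1] += 6.0 * np.sin(2 * np.pi * 0.25 * t[i0:i1]) + rng.normal(0, 1.0, i1 - i0)
    return PPGSegment("p", 0.0, FS, sig), beats, (i0, i1)


class TestReconstruction:
    def test_all_clean_mask_is_identity(self, rng):
        seg, _ = _clean_segment(rng)
        apply_sqa(seg)
        out = reconstruct_segment(seg)
        assert np.array_equal(out.samples, seg.samples)
        assert (out.quality != NOISY).all()

    def test_short_burst_reconstructed(self, rng):
        # 10-s burst aligned to the 5-s analysis grid, inside clean context
        seg, beats, (i0, i1) = _burst_segment(rng, 300.0, 10.0)
        apply_sqa(seg)
        assert (seg.quality[60:62] == NOISY).any()
        out = reconstruct_segment(seg)
        assert (out.quality != NOISY).all()
        ibi = detect_systolic_peaks(out)
        in_run = (ibi.beat_times >= 300.0) & (ibi.beat_times < 310.0)
        true_in_run = (beats >= 300.0) & (beats < 310.0)
        assert abs(in_run.sum() - true_in_run.sum()) <= 1

    def test_long_burst_left_noisy(self, rng):
        seg, _, _ = _burst_segment(rng, 300.0, 20.0)
        apply_sqa(seg)
        noisy_before = (seg.quality == NOISY).sum()
        out = reconstruct_segment(seg)
        assert (out.quality == NOISY).sum() == noisy_before
        assert not (out.quality == RECONSTRUCTED).any()

    def test_fully_noisy_returned_unchanged(self, rng):
        seg, _ = _clean_segment(rng, dur=60)
        seg.quality = np.full(12, NOISY, dtype=np.int8)
        out = reconstruct_segment(seg)
        assert out.flags.get("all_noisy")
        assert np.array_equal(out.samples, seg.samples)

    def test_requires_quality_mask(self, rng):
        seg, _ = _clean_segment(rng, dur=60)
        with pytest.raises(ValueError):
            reconstruct_segment(seg)


# ---------------------------------------------------------------------------
# peak detection

class TestPeakDetection:
    def test_zero_jitter_sixty_bpm(self, rng):
        sig, _, _ = simulate_ppg_segment(60, 0.0, 120, FS, None, rng)
        ibi = detect_systolic_peaks(PPGSegment("p", 0.0, FS, sig))
        assert len(ibi.ibis) > 100
        assert np.all(np.abs(ibi.ibis - 1000.0) <= 10.0)

    def test_flat_signal_empty_series(self):
        ibi = detect_systolic_peaks(PPGSegment("p", 0.0, FS, np.zeros(3000)))
        assert len(ibi.beat_times) == 0

    def test_no_clean_windows_empty_series(self, rng):
        seg, _ = _clean_segment(rng, dur=60)
        seg.quality = np.full(12, NOISY, dtype=np.int8)
        assert len(detect_systolic_peaks(seg).beat_times) == 0

    def test_beats_only_from_clean_windows(self, rng):
        seg, _ = _clean_segment(rng, dur=60)
        apply_sqa(seg)
        seg.quality[:6] = NOISY  # first 30 s manually masked
        ibi = detect_systolic_peaks(seg)
        assert ibi.beat_times.min() >= 30.0 - 1.0 / FS

    def test_ibi_validity_screen(self):
        beats = np.array([0.0, 0.8, 1.6, 1.75, 2.55, 5.0])
        ibi = IBISeries.from_beats(beats)
        # 150 ms interval out of range; following 800 ms is a >30% jump from
        # the last valid 800 ms? no - compares to previous *valid* (800) -> ok
        assert ibi.valid.tolist() == [True, True, False, True, False]


# ---------------------------------------------------------------------------
# HRV features

def _series_from_ibis(ibis_ms):
    beats = np.concatenate([[0.0], np.cumsum(np.asarray(ibis_ms) / 1000.0)])
    return IBISeries.from_beats(beats)


def _hrv_time_oracle(nn):
    """Independent direct-formula implementation (population SD)."""
    nn = np.asarray(nn, dtype=float)
    mean = nn.sum() / len(nn)
    sdnn = np.sqrt(((nn - mean) ** 2).sum() / len(nn))
    d = nn[1:] - nn[:-1]
    rmssd = np.sqrt((d ** 2).sum() / len(d))
    return dict(mean_nn=mean, hr=60000.0 / mean, sdnn=sdnn, rmssd=rmssd,
                cvsd=rmssd / mean, cvnn=sdnn / mean)


class TestHRV:
    def test_constant_ibis(self):
        ibi = _series_from_ibis([800.0] * 200)  # 160 s -> 2 complete minutes
        f = compute_hrv_features(ibi, 170.0)
        assert f.mean_nn == pytest.approx(800.0)
        assert f.hr == pytest.approx(75.0)
        assert f.sdnn == pytest.approx(0.0, abs=1e-9)
        assert f.rmssd == pytest.approx(0.0, abs=1e-9)
        assert f.cvsd == pytest.approx(0.0, abs=1e-12)
        assert f.sdann1 == pytest.approx(0.0, abs=1e-9)

    def test_alternating_ibis_hand_oracle(self):
        ibi = _series_from_ibis([800.0, 1000.0] * 6)
        f = compute_hrv_features(ibi, 11.0)
        assert f.rmssd == pytest.approx(200.0, abs=1e-9)
        assert f.sdnn == pytest.approx(100.0, abs=1e-9)
        assert f.cvsd == pytest.approx(200.0 / 900.0, abs=1e-9)

    def test_time_domain_oracle_equivalence(self, rng):
        for _ in range(100):
            n = int(rng.integers(12, 900))
            # bounded multiplicative walk: every interval passes the
            # physiological screen, so the oracle sees the same NN list
            nn = np.empty(n)
            nn[0] = rng.uniform(600, 1200)
            for i in range(1, n):
                nn[i] = np.clip(nn[i - 1] * (1 + rng.uniform(-0.2, 0.2)), 420, 1900)
            f = compute_hrv_features(_series_from_ibis(nn), nn.sum() / 1000.0 + 1)
            ora = _hrv_time_oracle(nn)
            for k, v in ora.items():
                assert getattr(f, k) == pytest.approx(v, abs=1e-9), k

    def test_too_few_ibis_missing_marked(self):
        f = compute_hrv_features(_series_from_ibis([800.0] * 5), 5.0)
        assert np.isnan(f.sdnn) and "reason" in f.flags

    def test_short_span_skips_spectral(self):
        f = compute_hrv_features(_series_from_ibis([800.0] * 20), 20.0)
        assert np.isnan(f.lf) and "spectral" in f.flags
        assert np.isfinite(f.sdnn)

    def test_lfn_hfn_normalisation_identity(self, rng):
        for _ in range(5):
            nn = 900 + 60 * rng.standard_normal(400)
            f = compute_hrv_features(_series_from_ibis(nn), 400.0)
            if np.isfinite(f.lf) and (f.lf + f.hf) > 0:
                assert f.lfn + f.hfn == pytest.approx(1.0, abs=1e-9)
                assert f.lfn == pytest.approx(f.lf / (f.lf + f.hf), abs=1e-12)

    def test_spectral_against_independent_periodogram(self, rng):
        """Band powers match a hand-rolled Hann/overlap periodogram-average
        oracle (no scipy.signal) within 2 %."""
        nn = 900 + 50 * np.sin(2 * np.pi * 0.1 * np.arange(700) * 0.9) \
            + 20 * rng.standard_normal(700)
        ibi = _series_from_ibis(nn)
        f = compute_hrv_features(ibi, nn.sum() / 1000.0 + 1)

        nn_t = ibi.beat_times[1:][ibi.valid]
        vals = ibi.valid_nn()
        ts = np.arange(nn_t[0], nn_t[-1], 1.0 / INTERP_HZ)
        x = np.interp(ts, nn_t, vals)
        nper = min(int(WELCH_SEG_S * INTERP_HZ), len(x))
        step = nper - nper // 2
        win = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nper) / nper)  # periodic Hann
        psds = []
        for s in range(0, len(x) - nper + 1, step):
            seg = x[s:s + nper]
            # linear detrend
            tt = np.arange(nper)
            b1, b0 = np.polyfit(tt, seg, 1)
            seg = seg - (b1 * tt + b0)
            spec = np.abs(np.fft.rfft(seg * win)) ** 2 / (INTERP_HZ * (win ** 2).sum())
            spec[1:-1] *= 2
            psds.append(spec)
        pxx = np.mean(psds, axis=0)
        freqs = np.fft.rfftfreq(nper, 1.0 / INTERP_HZ)
        df = freqs[1] - freqs[0]
        lf = pxx[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])].sum() * df
        hf = pxx[(freqs >= HF_BAND[0]) & (freqs < HF_BAND[1])].sum() * df
        assert f.lf == pytest.approx(lf, rel=0.02)
        assert f.hf == pytest.approx(hf, rel=0.02)

    def test_sdann5_low_confidence_flag(self):
        nn = 800 + 50 * np.sin(np.arange(900))
        f = compute_hrv_features(_series_from_ibis(nn), 720.0)
        assert np.isfinite(f.sdann5)
        assert f.flags.get("sdann5_low_confidence")
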