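"""Clean one noisy PPG segment and extract HR/HRV features.

Simulates a 12-minute wrist PPG segment with a motion-artifact burst,
runs signal-quality assessment, reconstruction and peak detection, and
compares the recovered HRV against the generator's ground truth.
"""

import numpy as np

from lonesense.ppg import (NOISY, PPGSegment, apply_sqa, compute_hrv_features,
                           detect_systolic_peaks, reconstruct_segment)
from lonesense.synth import NoiseSpec, simulate_ppg_segment

rng = np.random.default_rng(3)
sig, beats, mask = simulate_ppg_segment(
    mean_hr=72, hrv_sd_ms=45, duration_s=720, fs=25,
    noise_spec=NoiseSpec(burst_rate=1.0, short_frac=1.0), rng=rng)

seg = PPGSegment("P01", 0.0, 25.0, sig)
apply_sqa(seg)
n_noisy = int((seg.quality == NOISY).sum())
print(f"SQA: {n_noisy}/{len(seg.quality)} windows noisy "
      f"(true noise covers {mask.mean():.1%} of samples)")

seg = reconstruct_segment(seg)
for run in seg.flags["reconstruction"]:
    print(f"  windows {run['windows']}: {run['action']}")

ibi = detect_systolic_peaks(seg)
feats = compute_hrv_features(ibi, 720.0)
true_nn = np.diff(beats) * 1000
print(f"beats: {len(ibi.beat_times)} detected vs {len(beats)} true; "
      f"{ibi.n_valid} valid IBIs")
print(f"MeanNN {feats.mean_nn:6.1f} ms (true {true_nn.mean():6.1f})  "
      f"SDNN {feats.sdnn:5.1f} ms (true {np.std(true_nn):5.1f})")
print(f"RMSSD {feats.rmssd:6.1f} ms  CVSD {feats.cvsd:.3f}  "
      f"LF/HF {feats.lf:.0f}/{feats.hf:.0f} ms^2 (LFn {feats.lfn:.2f})")
print("Recovered HRV should track the truth within a few ms despite the burst.")
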