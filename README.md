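# lonesense

Objective detection of momentary loneliness from multi-device passive
sensing, as a tested, reusable Python pipeline.

Loneliness fluctuates over hours and days, but it is usually measured with
retrospective questionnaires. Ambulatory protocols instead pair brief
in-the-moment self-reports (EMA: "How lonely do you feel right now?",
0-100, five times a day) with passive streams from devices people already
wear and carry: a smartwatch recording photoplethysmography (PPG) for
heart rate and heart-rate variability, a smartphone logging GPS mobility,
calls, messages, app notifications and screen use, and a smart ring
reporting nightly sleep and physiology summaries. `lonesense` implements
the full analysis chain for such a protocol, for researchers in digital
phenotyping and mobile health who want each stage testable in isolation:

- **`lonesense.synth`** — a synthetic cohort generator with complete
  ground truth (latent loneliness trajectories, true heart beats and noise
  masks, true homes/places/visits, planted feature-label couplings), so
  every downstream stage can be validated without any data download;
- **`lonesense.ppg`** — the watch chain: signal-quality assessment
  (five features per window: IQR, SD of the PSD, cycle-energy range,
  cycle-template distance and correlation), reconstruction of noisy runs
  shorter than 15 s by phase-locked template tiling, systolic peak
  detection with sub-sample refinement, and HR/HRV features (MeanNN,
  SDNN, RMSSD, CVSD, CVNN, LF, HF, LFn, HFn, SDANN1/5);
- **`lonesense.behavior`** — home and significant-place detection from
  stay points, ten mobility features, call/message/notification-category
  and screen-usage features;
- **`lonesense.assemble`** — the EMA-aligned modeling table: per-feature
  look-back windows (4-48 h) selected by correlation with the scores, a
  strict >30 % missingness drop rule, two imputation methods with a
  majority vote, per-participant median-split labels
  (lonely ⇔ score > median), and per-participant train-only
  z-normalization;
- **`lonesense.model`** — one random forest per participant with a
  temporal holdout (the participant's most recent 50 % of rows is the
  test set; everything else trains), pooled confusion counts, accuracy /
  precision / recall / F1 / MSE = (FP+FN)/N / rank AUC, and per-device
  ablation (ring vs watch vs phone vs all);
- **`lonesense.explain`** — a native path-dependent TreeSHAP
  implementation (exact per-record Shapley attributions in probability
  space, local accuracy checked at call time) aggregated to
  participant × feature importance matrices and signed summaries.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from lonesense import (simulate_cohort, strong_coupling_config, build_streams,
                       assemble_features, evaluate_ablation, Hyperparams)

cfg = strong_coupling_config(n_participants=8, n_days=14, ppg_mode="summary", seed=33)
cohort = simulate_cohort(cfg)                       # EMA + watch + phone + ring
asm = assemble_features(build_streams(cohort), cohort.ema)
for subset, res in evaluate_ablation(asm, Hyperparams(), seed=33).items():
    p = res.pooled
    print(f"{'+'.join(subset):22s} acc {p.accuracy:.3f}  f1 {p.f1:.3f}  auc {p.auc:.3f}")
```

prints:

```
ring                   acc 0.558  f1 0.553  auc 0.530
watch                  acc 0.785  f1 0.763  auc 0.908
phone                  acc 0.677  f1 0.592  auc 0.812
ring+watch+phone       acc 0.792  f1 0.771  auc 0.905
```

Each row is a detector trained and tested on one device's features only
(last row: all devices). Accuracy is the pooled fraction of correctly
classified test EMAs across all personal models; the all-device row
matching or beating the best single device is the multimodality gain, and
the ring being weakest reflects that nightly summaries reach the next
day's labels only through the latent process's day-to-day persistence.
The scripts in `examples/` walk through each capability (cohort
simulation, PPG cleaning, behavioral features, assembly, evaluation,
SHAP explanations) in a few lines each.

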