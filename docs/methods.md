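# Methods

`lonesense` implements a fully objective pipeline for detecting momentary
loneliness from passive multi-device sensing: a wrist device recording
photoplethysmography (PPG), a smartphone logging behavior (GPS, calls,
messages, notifications, screen), and a ring reporting one nightly
sleep/physiology summary. Self-reported loneliness (0-100, five
ecological momentary assessments per day) provides the labels. Because no
public dataset exists for this protocol, the package ships a synthetic
cohort generator with full ground truth; every claim the test suite makes
is a claim about recovery of that known truth.

## Synthetic cohort model

**Latent loneliness.** Each participant carries a stationary daily AR(1)
process `z_d = φ z_{d-1} + √(1-φ²) ε` with unit variance (default
φ = 0.7), plus independent within-day wobble (SD 0.25). Loneliness
fluctuates over days much more than within a day, which is what makes
look-back feature windows of hours-to-days informative. Observed scores
are `clip(round(20·z + 50 + N(0, 3)), 0, 100)`. Prompts follow an
interval-contingent schedule: five windows per day centred 3.5 h apart
(08:30-22:30), ±25 min jitter, so consecutive prompts are at most ~4 h
apart. Each response is independently missing with probability 0.08.

**Couplings.** Six channels tie the streams to the latent state, each with
a configurable standardized effect size (the shipped "strong" condition
sets all to 1):

| channel | expression per 1 SD of latent loneliness |
|---|---|
| `hrv` (watch) | daytime HR +4 bpm; IBI jitter SD ×exp(-0.35) from 45 ms |
| `nocturnal_hr` (ring) | nightly HR +3 bpm; nightly RMSSD ×exp(-0.30) |
| `home_stay` (phone) | away-from-home dwell ×exp(-0.40) |
| `n_places` (phone) | visited-place rate 2.2 - 0.9·z (Poisson mean) |
| `communication` (phone) | call/message/notification rates ×exp(-0.30) |
| `social_notifications` (phone) | extra Social-app notifications ×exp(+0.35·z), sign configurable |

Event rates all scale with `exp(sociability)`, so the communication
channel touches every phone event stream; the only features untouched by
any channel are the ring's sleep duration, onset latency, and activity
minutes - these serve as planted nulls for the explainability checks.
Nights reflect the *same day's* latent state and are reported the next
morning, so ring features predict the following day's labels only through
the AR(1) autocorrelation; the ring is by construction the weakest device.

**PPG.** Beats are placed with Gaussian IBI jitter; each beat contributes
a systolic Gaussian plus a smaller dicrotic bump (amplitudes 1.0/0.35,
widths 9 %/14 % of the local IBI) on a faint respiratory baseline; default
sampling 25 Hz, 12-min segments every 2 h. Motion bursts add large
baseline wander (0.1-0.5 Hz, amplitude 3-8) plus broadband noise; burst
durations mix short (4-12 s) and long (18-45 s) so both the
reconstruction and the discard paths are exercised. The generator records
true beat times and noise masks.

**GPS.** An abstract plane with lat/lon semantics: home anchor, 4
candidate places 0.6-3 km away, nights at home, straight-line transit at
6 m/s, fixes every 2 min while moving / 5 min while still, isotropic
10-m jitter. **Events** are Poisson with lognormal/exponential durations;
notification categories are drawn from a plausible mix over the 18-app
category taxonomy shipped with the package. **Ring nights** are one row
per night; 5 % of nights are missing, and contiguous watch dropout gaps
remove ~8 % of PPG segments.

What the generator does **not** emulate: real PPG morphology variation
(it has a fixed two-Gaussian shape), accelerometer-correlated artifacts,
realistic geography or transport modes, content-dependent phone use,
circadian structure in event rates beyond the day window, and any feedback
of behavior on the latent state. Passing tests therefore show the pipeline
recovers signal with these simplified stream models, not that the same
accuracy would be reached on real cohorts.

## PPG cleaning chain

1. **Signal-quality assessment.** Five features per 5-s analysis window:
   interquartile range, SD of the periodogram, range of per-cycle energy,
   mean Euclidean distance of length-normalised cycles to their template,
   and mean cycle-template correlation. A window is noisy when a majority
   of features cross their thresholds (strict inequalities; an
   any-crossing rule is available). Thresholds were calibrated once by
   per-feature error minimisation on a 2,400-window synthetic calibration
   set and are frozen as defaults; the shipped 400-window benchmark
   (different seed) scores ≈97 % agreement with the generator masks. The
   5-s window is deliberately finer than the 15-s reconstruction
   threshold; with coarser windows no noisy run could ever qualify for
   reconstruction.
2. **Reconstruction.** Noisy runs shorter than 15 s bounded by clean
   windows are replaced by tiling a heart-cycle template built from
   neighbouring clean cycles. Tiles are phase-locked to the bounding
   clean anchor beats (anchored half a window away from the run, because
   burst edges leak into adjacent clean-labelled windows), carry
   deterministic pseudo-random IBI jitter matched to the local IBI spread
   (a zero-variability insertion would bias SDNN/RMSSD low), and
   cross-fade linearly into the surrounding signal. Runs ≥ 15 s and runs
   touching a segment edge stay noisy and are excluded downstream. On
   single-burst benchmarks this reconstruction yields a smaller mean
   HRV error than simply discarding the noisy windows.
3. **Peak detection.** 0.5-8 Hz zero-phase band-pass, local maxima above
   0.4× the rolling 75th-percentile amplitude with a 300-ms refractory,
   parabolic sub-sample refinement (essential at 25 Hz, where the raw
   sampling grid alone is 40 ms), beats kept only in clean or
   reconstructed windows. IBIs outside 300-2000 ms, or changing more
   than 30 % from the previous valid interval, are flagged invalid.
4. **HRV features.** Time domain (MeanNN, HR, SDNN, RMSSD, CVSD, CVNN)
   over valid NN intervals with the population (ddof 0) SD convention
   throughout; ≥10 valid intervals required. Spectral LF [0.04, 0.15) and
   HF [0.15, 0.4) Hz in ms² from a 4-Hz interpolated NN series (linear
   detrend, Hann Welch, 120-s segments, 50 % overlap), ≥2 min of valid
   span required; LFn/HFn are power-normalised. SDANN1/SDANN5 are SDs of
   per-1-min/per-5-min mean NN over complete bins; on a 12-min segment
   SDANN5 has only two bins and is flagged low-confidence.

## Behavioral features

Stay points use the classic scan (fixes within 150 m of the anchor for
≥10 min), merged into places by 150-m centroid distance; home is the
dominant night-time (00:00-06:00) cluster. The ten mobility features
follow the standard digital-phenotyping set (latitude variance, speed
mean/variance with a 10-min gap rule, number of places, home and outdoor
duration, mean/SD/longest non-home stay, travel distance); the four
"≥2 places" features are missing when fewer than two places were visited
in the window. Travel distance is measured on the stay-collapsed
trajectory (stays replaced by their centroids): a raw fix-to-fix path sum
accumulates hundreds of spurious metres per stationary hour from GPS
jitter alone and systematically overestimates travel. Phone-log features
are call counts/duration sums per category, message counts per direction,
notification counts per the 18 app categories (unmapped packages fall
back to Unknown), and screen unlock count plus screen-on time from
sanitised unlock→lock intervals clipped at window edges.

## Dataset assembly

For each feature, candidate look-back windows {4, 8, 12, 24, 36, 48} h
ending at the EMA timestamp are aggregated (means for continuous
signals, sums for events, window-level computation for mobility; nightly
ring values take the most recent night within 36 h and are exempt from
window selection). The window with the largest |Pearson r| against the
0-100 scores wins; ties go to the shorter window; features with no
computable correlation default to 24 h with a flag. Features missing in
more than 30 % of rows (strictly) are dropped. Two imputations are
compared per feature - A: mean of up to two preceding and two succeeding
valid values of the same participant; B: the participant's mean of all
valid values - and the method with the larger |r| for the majority of
features is applied to all features (ties favour B). Labels are a
per-participant median split (lonely iff score > median; ties to
not-lonely); participants with under four responses or one-class labels
are excluded.

All selection statistics (windows, imputation vote, pooled fallback
means) are computed on the earliest 50 % of every participant's EMAs.
These rows sit inside the training side of *every* per-participant
temporal split, so no selection ever sees a test row - deliberately
stricter than computing them on all data.

## Detection and evaluation

One random forest per target participant: training set = the target's
earliest ⌈n/2⌉ labeled rows plus all rows of all other participants; test
set = the target's most recent rows. Features are z-normalized per
participant with statistics from that participant's training rows only
(constant columns get SD 1 and a flag). Defaults: 100 trees, √p features
per split, minimum leaf 5, fixed seeds derived per participant; at these
data sizes accuracy is flat between 100 and 300 trees, so the smaller
ensemble is used. Predicted probability is the ensemble-averaged leaf
class-1 fraction; the decision threshold is 0.5 with ties to the
not-lonely class. Confusion counts are pooled over all test rows before
computing accuracy, precision, recall, F1, MSE = (FP+FN)/N (so
accuracy + MSE = 1 identically), and a rank-statistic AUC with mid-ranked
ties. Device ablation re-runs the whole evaluation on feature subsets by
device of origin (ring / watch / phone / all); the imputation-method vote
is re-taken on the restricted feature set, while per-feature window
choices are unaffected by subsetting.

## Explainability

Path-dependent TreeSHAP is implemented natively for scikit-learn forests:
along each root-to-leaf path the algorithm maintains the unique split
features with their cover ("zero") and decision ("one") fractions and a
permutation-weight accumulator, and accumulates attributions at the
leaves. Attributions are computed in probability space, so
`base_value + Σ attributions` equals `predict_proba` for every record
(checked to 1e-6 at call time); positive values push toward the lonely
class. On small ensembles the implementation is tested to equal an
exhaustive Shapley computation with path-dependent conditional
expectations over all feature subsets. Importance is aggregated as mean
|SHAP| per (participant, feature), ranked by the cross-participant mean,
with per-participant signed summaries (mean SHAP and the correlation
between feature value and attribution). The recursion is jit-compiled
with numba when available and runs as pure Python otherwise.

## Problem sizes and numerical choices

The shipped strong-coupling study condition is 30 participants × 56 days
(five prompts/day, 12 two-hour PPG segments/day); large-cohort runs
stream each PPG segment through the cleaning chain at generation time and
retain only its HRV row, keeping memory under ~1 GB. Component benchmarks
use 100 twelve-minute segments (beat recovery), ~100 single-burst
segments (reconstruction vs discard), a 400-window SQA benchmark, 30
participants × 5 days of GPS (home detection), and 100 seeded replicates
(window-selection recovery). The explainability replicates use compact
8-participant × 10-day cohorts in summary-PPG mode (HRV computed from
true beat times), since those checks concern the modeling layers, not the
waveform chain. The zero-coupling control uses 12 participants × 20 days.

Degenerate inputs are handled explicitly: flat PPG yields no beats; fewer
than two detectable cycles makes an SQA window "noisy" by definition;
undefined classification ratios are NaN with flags; constant training
features z-normalize to zero with a flag. A note on the null condition:
with median-split labels, a temporal holdout, and an autocorrelated
latent process, train- and test-half base rates are anti-correlated, so
null-cohort accuracy sits slightly *below* 0.5 (~0.45-0.50) rather than
at it; this is a property of the evaluation protocol, not a bug.

## Known limitations

The SQA thresholds are calibrated to this generator's noise model and
would need recalibration for real wrist data. The reconstruction
stand-in restores plausible, variability-matched beats but cannot recover
the true beat times inside a burst. Oura-style sleep summaries are
consumed as given - no sleep staging is modelled. The per-participant
median used for labels is computed over the full score series (the
protocol's reading of "balanced labels per personal model"); a
train-only-median mode is available via `make_labels(..., mode="train")`
for fully leakage-free labeling.
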