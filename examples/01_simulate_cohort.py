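"""Simulate a small multi-device cohort and look at its streams.

Generates 3 participants for 5 days with all coupling channels active,
prints what each stream contains, and writes the cohort to disk in the
package's plain-text formats.
"""

from lonesense import simulate_cohort, strong_coupling_config
from lonesense.io import write_cohort

cfg = strong_coupling_config(n_participants=3, n_days=5, seed=7,
                             store_ppg_segments=True)
cohort = simulate_cohort(cfg)

print(f"EMA responses:   {len(cohort.ema)} rows "
      f"(scores {cohort.ema['score'].min()}-{cohort.ema['score'].max()} on the 0-100 scale)")
print(f"PPG segments:    {len(cohort.ppg_segments)} x "
      f"{cfg.ppg_segment_minutes:.0f} min at {cfg.ppg_fs:.0f} Hz")
print(f"GPS fixes:       {len(cohort.gps)}")
print(f"Phone events:    {len(cohort.events)} "
      f"({cohort.events['type'].nunique()} event types)")
print(f"Ring nights:     {len(cohort.sleep)}")
print(f"Ground truth:    latent states for {len(cohort.ground_truth.latent)} prompts, "
      f"true beats for {len(cohort.ground_truth.beats)} segments")

out = write_cohort(cohort, "scratch/example_cohort")
print(f"written to {out}/ (ema.csv, gps.csv, events.csv, sleep.csv, ppg/, ground_truth.json)")
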