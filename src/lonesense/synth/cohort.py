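"""End-to-end synthetic cohort generation with full ground truth.

The generator emulates a multi-device ambulatory protocol: five EMA prompts
per day, a watch that wakes every two hours to record twelve minutes of PPG,
continuous phone logging (calls, messages, notifications, screen, GPS), and
a ring that reports one sleep/physiology summary per night.  A per
participant latent loneliness process couples to the streams through
configurable per-channel effect sizes, so every downstream stage can be
validated against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import CohortConfig
from ..ppg.hrv import HRV_FEATURES
from ..ppg.pipeline import PPGPipelineConfig, hrv_from_beats, hrv_stream, process_segment
from ..ppg.segment import PPGSegment
from .ema import latent_trajectory, schedule_windows, simulate_ema_day
from .events import EventRates, default_category_mix, simulate_events_day
from .location import Visit, make_places, simulate_location_day
from .ppg import NoiseSpec, simulate_beats, simulate_ppg_segment

DAY_S = 86400.0

SLEEP_FEATURES = ["sleep_nocturnal_hr", "sleep_nocturnal_rmssd", "sleep_duration_h",
                  "sleep_onset_latency_min", "sleep_activity_high_min",
                  "sleep_activity_med_min", "sleep_activity_low_min"]


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    homes: dict[str, tuple[float, float]]
    place_centroids: dict[str, list[tuple[float, float]]]
    visits: dict[tuple[str, int], list[Visit]]
    daily: pd.DataFrame          # per participant-day latent + channel drivers
    latent: pd.DataFrame         # per prompt: participant, day, slot, latent
    segments: pd.DataFrame       # per PPG segment: true beat stats
    beats: dict[tuple[str, float], np.ndarray]        # (pid, t0) -> beat times
    noise_masks: dict[tuple[str, float], np.ndarray]  # (pid, t0) -> sample mask
    coupling: dict[str, float]


@dataclass
class Cohort:
    config: CohortConfig
    ema: pd.DataFrame
    gps: pd.DataFrame
    events: pd.DataFrame
    sleep: pd.DataFrame
    ppg_segments: list[PPGSegment]
    watch_hrv: pd.DataFrame | None
    ground_truth: GroundTruth

    def watch_hrv_stream(self, ppg_config: PPGPipelineConfig | None = None) -> pd.DataFrame:
        """The per-segment HRV feature stream.

        In ``waveform`` mode this is the output of the full cleaning chain -
        run lazily here when segments were retained, or already computed
        during generation when ``store_ppg_segments`` is off.  In ``summary``
        mode it is the stream derived from true beats.
        """
        if self.watch_hrv is not None:
            return self.watch_hrv
        return hrv_stream(self.ppg_segments, ppg_config)


def _hrv_row(pid: str, t0: float, feats) -> dict:
    row = {"participant_id": pid, "t": t0}
    row.update({f"hrv_{k}": v for k, v in feats.to_dict().items() if k in HRV_FEATURES})
    return row


def _true_ibi_stats(beats: np.ndarray) -> tuple[float, float, int]:
    if len(beats) < 2:
        return np.nan, np.nan, len(beats)
    ibis = np.diff(beats) * 1000.0
    return float(ibis.mean()), float(np.std(ibis)), len(beats)


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full multi-stream cohort plus ground truth."""
    root = np.random.SeedSequence(config.seed)
    p_seeds = root.spawn(config.n_participants)
    eff = config.effect

    ema_rows, gps_frames, event_frames, sleep_rows = [], [], [], []
    daily_rows, latent_rows, seg_rows = [], [], []
    segments: list[PPGSegment] = []
    summary_rows = []
    homes, centroids, visits_gt = {}, {}, {}
    beats_gt, masks_gt = {}, {}

    seg_duration = config.ppg_segment_minutes * 60.0
    noise = NoiseSpec(burst_rate=config.noise_burst_rate)
    windows = schedule_windows(config.ema_per_day)
    mix = default_category_mix()

    for p_idx, p_seed in enumerate(p_seeds):
        pid = f"P{p_idx + 1:02d}"
        rng = np.random.default_rng(p_seed)
        home = (33.6 + rng.uniform(-0.3, 0.3), -117.8 + rng.uniform(-0.3, 0.3))
        places = make_places(home, 4, rng)
        homes[pid] = home
        centroids[pid] = places
        sociability_base = rng.normal(0.0, 0.25)
        daily, lat_ema = latent_trajectory(config.n_days, config.ema_per_day, rng,
                                           config.latent_ar, config.within_day_sd)

        # contiguous watch dropout gaps totalling ~watch_dropout_p of segments
        n_seg_total = config.n_days * config.segments_per_day
        seg_missing = np.zeros(n_seg_total, dtype=bool)
        if config.watch_dropout_p > 0:
            mean_gap = 5.0
            p_start = config.watch_dropout_p / mean_gap
            s = 0
            while s < n_seg_total:
                if rng.uniform() < p_start:
                    gap = int(rng.integers(2, 9))
                    seg_missing[s:s + gap] = True
                    s += gap
                else:
                    s += 1

        for d in range(config.n_days):
            z = daily[d]
            day_off = d * DAY_S

            # --- EMA ---
            for slot, lz in enumerate(lat_ema[d]):
                latent_rows.append((pid, d, slot, lz))
            for t, score in simulate_ema_day(lat_ema[d], windows, rng,
                                             config.score_scale, config.score_offset,
                                             config.score_noise_sd, config.ema_missing_p,
                                             day_off):
                ema_rows.append((pid, t, score))

            # --- watch PPG ---
            hrv_sd = float(np.clip(45.0 * np.exp(-0.35 * eff("hrv") * z) + rng.normal(0, 2),
                                   12.0, 120.0))
            mean_hr = float(np.clip(72.0 + 4.0 * eff("hrv") * z + rng.normal(0, 1.5),
                                    45.0, 110.0))
            for s_idx in range(config.segments_per_day):
                t0 = day_off + s_idx * config.ppg_period_hours * 3600.0
                if seg_missing[d * config.segments_per_day + s_idx]:
                    continue
                if config.ppg_mode == "waveform":
                    sig, beats, mask = simulate_ppg_segment(
                        mean_hr, hrv_sd, seg_duration, config.ppg_fs, noise, rng)
                    beats_gt[(pid, t0)] = beats
                    seg = PPGSegment(pid, t0, config.ppg_fs, sig)
                    if config.store_ppg_segments:
                        segments.append(seg)
                        masks_gt[(pid, t0)] = mask
                    else:
                        # stream the segment through the full cleaning chain
                        # now and keep only its HRV row (bounded memory)
                        feats, _, _ = process_segment(seg)
                        summary_rows.append(_hrv_row(pid, t0, feats))
                else:
                    beats = simulate_beats(mean_hr, hrv_sd, seg_duration, rng)
                    beats_gt[(pid, t0)] = beats
                    summary_rows.append(_hrv_row(pid, t0, hrv_from_beats(beats, seg_duration)))
                m, sd_, nb = _true_ibi_stats(beats)
                seg_rows.append((pid, t0, m, sd_, nb))

            # --- phone GPS ---
            lam = float(np.clip(2.2 - 0.9 * eff("n_places") * z, 0.2, 6.0))
            n_visits = int(rng.poisson(lam))
            dwell_f = float(np.clip(np.exp(-0.4 * eff("home_stay") * z), 0.3, 2.5))
            ts, lat_, lon_, truth = simulate_location_day(
                home, places, lam, rng, n_visits=n_visits,
                dwell_range_min=(40.0 * dwell_f, 120.0 * dwell_f), day_offset_s=day_off)
            gps_frames.append(pd.DataFrame(
                {"participant_id": pid, "t": ts, "lat": lat_, "lon": lon_}))
            visits_gt[(pid, d)] = truth.visits

            # --- phone events ---
            soc = sociability_base - 0.30 * eff("communication") * z
            social_rate = 8.0 * np.exp(0.35 * eff("social_notifications") * z)
            rates = EventRates(extra_category="Social", extra_rate=social_rate)
            event_frames.append(simulate_events_day(soc, mix, rng, rates, pid, day_off))

            # --- ring night (night d -> reported morning d+1) ---
            noct_hr = 58.0 + 3.0 * eff("nocturnal_hr") * z + rng.normal(0, 1.2)
            noct_rmssd = float(np.clip(52.0 * np.exp(-0.30 * eff("nocturnal_hr") * z)
                                       + rng.normal(0, 3), 8.0, 150.0))
            ring_present = rng.uniform() >= config.ring_missing_p
            if d < config.n_days - 1 and ring_present:
                sleep_rows.append((pid, d, (d + 1) * DAY_S + 8 * 3600.0, noct_hr, noct_rmssd,
                                   float(np.clip(7.3 + rng.normal(0, 0.7), 3.5, 11.0)),
                                   float(np.clip(np.exp(rng.normal(2.7, 0.5)), 2.0, 90.0)),
                                   float(rng.poisson(25)), float(rng.poisson(90)),
                                   float(rng.poisson(300))))

            daily_rows.append((pid, d, z, hrv_sd, mean_hr, n_visits,
                               sum(v.end - v.start for v in truth.visits) / 60.0,
                               truth.travel_m, float(np.exp(soc)), float(social_rate),
                               float(noct_hr), noct_rmssd))

    ema = pd.DataFrame(ema_rows, columns=["participant_id", "t", "score"])
    gps = pd.concat(gps_frames, ignore_index=True) if gps_frames else pd.DataFrame()
    events = pd.concat(event_frames, ignore_index=True) if event_frames else pd.DataFrame()
    sleep = pd.DataFrame(sleep_rows, columns=["participant_id", "night", "t"] + SLEEP_FEATURES)
    daily = pd.DataFrame(daily_rows, columns=[
        "participant_id", "day", "latent", "true_ibi_sd_ms", "true_mean_hr", "n_visits",
        "away_min", "travel_m", "comm_mult", "social_rate", "nocturnal_hr", "nocturnal_rmssd"])
    latent = pd.DataFrame(latent_rows, columns=["participant_id", "day", "slot", "latent"])
    seg_df = pd.DataFrame(seg_rows, columns=["participant_id", "t", "true_mean_ibi_ms",
                                             "true_ibi_sd_ms", "n_beats"])
    gt = GroundTruth(homes, centroids, visits_gt, daily, latent, seg_df,
                     beats_gt, masks_gt, dict(config.coupling))
    summary = pd.DataFrame(summary_rows) if summary_rows else None
    return Cohort(config, ema, gps, events, sleep, segments, summary, gt)
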