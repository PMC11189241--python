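"""On-disk formats for the cohort streams.

Tables are plain CSV with ISO-8601 UTC timestamps; PPG segments are one
plain-text file each (a small header followed by one sample per line).
Internally all times are float seconds since the cohort reference epoch.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ppg.segment import PPGSegment


def _epoch(start_time_utc: str) -> pd.Timestamp:
    return pd.Timestamp(start_time_utc)


def seconds_to_iso(t, start_time_utc: str) -> pd.Series:
    ep = _epoch(start_time_utc)
    return pd.Series(ep + pd.to_timedelta(np.asarray(t, float), unit="s")).dt.strftime(
        "%Y-%m-%dT%H:%M:%S.%fZ")


def iso_to_seconds(ts, start_time_utc: str) -> np.ndarray:
    ep = _epoch(start_time_utc)
    return (pd.to_datetime(ts) - ep).dt.total_seconds().to_numpy()


def write_ppg_segment(seg: PPGSegment, path: Path, start_time_utc: str) -> None:
    ts = seconds_to_iso([seg.start_time], start_time_utc).iloc[0]
    with open(path, "w") as fh:
        fh.write(f"# participant_id: {seg.participant_id}\n")
        fh.write(f"# start_time: {ts}\n")
        fh.write(f"# fs_hz: {seg.fs:g}\n")
        np.savetxt(fh, seg.samples, fmt="%.6f")


def read_ppg_segment(path: Path, start_time_utc: str) -> PPGSegment:
    header = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
        samples = np.loadtxt(fh, ndmin=1)
    t0 = float(iso_to_seconds(pd.Series([header["start_time"]]), start_time_utc)[0])
    return PPGSegment(header["participant_id"], t0, float(header["fs_hz"]), samples)


def write_cohort(cohort, outdir) -> Path:
    """Write every stream of a simulated cohort (plus the JSON-serialisable
    part of its ground truth) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    start = cohort.config.start_time_utc

    ema = cohort.ema.copy()
    ema["timestamp"] = seconds_to_iso(ema.pop("t"), start)
    ema.rename(columns={"score": "loneliness_score"})[
        ["participant_id", "timestamp", "loneliness_score"]].to_csv(
        outdir / "ema.csv", index=False)

    gps = cohort.gps.copy()
    gps["timestamp"] = seconds_to_iso(gps.pop("t"), start)
    gps[["participant_id", "timestamp", "lat", "lon"]].to_csv(outdir / "gps.csv", index=False)

    ev = cohort.events.copy()
    ev["timestamp"] = seconds_to_iso(ev.pop("t"), start)
    ev[["participant_id", "timestamp", "type", "duration_s", "app_package"]].to_csv(
        outdir / "events.csv", index=False)

    sl = cohort.sleep.copy()
    sl["timestamp"] = seconds_to_iso(sl.pop("t"), start)
    sl.to_csv(outdir / "sleep.csv", index=False)

    ppg_dir = outdir / "ppg"
    ppg_dir.mkdir(exist_ok=True)
    for i, seg in enumerate(cohort.ppg_segments):
        write_ppg_segment(seg, ppg_dir / f"{seg.participant_id}_{i:05d}.txt", start)

    gt = cohort.ground_truth
    payload = {
        "coupling": gt.coupling,
        "homes": {pid: list(map(float, h)) for pid, h in gt.homes.items()},
        "place_centroids": {pid: [list(map(float, c)) for c in cs]
                            for pid, cs in gt.place_centroids.items()},
        "visits": {f"{pid}/{day}": [[v.place_idx, v.start, v.end] for v in vs]
                   for (pid, day), vs in gt.visits.items()},
        "daily": gt.daily.to_dict(orient="list"),
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return outdir


def read_table(path: Path, start_time_utc: str, time_col: str = "timestamp") -> pd.DataFrame:
    df = pd.read_csv(path)
    df["t"] = iso_to_seconds(df[time_col], start_time_utc)
    return df.drop(columns=[time_col])
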