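"""Build the EMA-aligned modeling table.

Pipeline: per-feature look-back aggregation over a grid of candidate window
lengths (4-48 h), per-feature optimum-window selection by absolute Pearson
correlation with the 0-100 loneliness score, a strict >30 % missingness drop
rule, two imputation methods (nearest-neighbours vs participant mean) with a
majority-vote choice between them, per-participant median-split labels, and
per-participant train-only z-normalization.

All selection statistics (window choice, imputation choice, fallback means)
are computed on the earliest 50 % of every participant's EMAs - rows that are
in the training side of every per-participant temporal split - so no choice
ever sees a test row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior.location import LOCATION_FEATURES, build_context, location_features
from .behavior.phone import (CALL_DURATION_TYPES, CALL_TYPES, CATEGORIES,
                             load_app_category_map, screen_sessions)
from .errors import DataError
from .ppg.hrv import HRV_FEATURES

WINDOW_GRID_H = (4, 8, 12, 24, 36, 48)
DEFAULT_WINDOW_H = 24
MISSING_THRESHOLD = 0.30
MAX_SLEEP_LOOKBACK_S = 36 * 3600.0

DEVICE_RING = "ring"
DEVICE_WATCH = "watch"
DEVICE_PHONE = "phone"
ALL_DEVICES = (DEVICE_RING, DEVICE_WATCH, DEVICE_PHONE)


# ---------------------------------------------------------------------------
# feature streams

@dataclass
class StreamSet:
    """Per-feature stream data keyed by participant, ready for windowed
    aggregation.

    ``point`` features hold ``(t, values)`` arrays and an aggregation kind
    ('mean' for continuous signals, 'sum' for event counts/durations);
    ``interval`` features hold (start, end) arrays whose window value is the
    clipped overlap; ``last`` features (nightly summaries) take the most
    recent value; ``window`` features are computed by a callable per window.
    """

    point: dict[str, tuple[str, str, dict]] = field(default_factory=dict)
    interval: dict[str, tuple[str, dict]] = field(default_factory=dict)
    last: dict[str, tuple[str, dict]] = field(default_factory=dict)
    window: dict[str, tuple[str, dict]] = field(default_factory=dict)

    def devices(self) -> dict[str, str]:
        out = {}
        for name, (device, _, _) in self.point.items():
            out[name] = device
        for group in (self.interval, self.last, self.window):
            for name, (device, _) in group.items():
                out[name] = device
        return out

    def names(self) -> list[str]:
        return list(self.devices())


def _by_pid(df: pd.DataFrame, value_col: str) -> dict:
    out = {}
    for pid, sub in df.groupby("participant_id", sort=True):
        sub = sub.sort_values("t", kind="stable")
        out[pid] = (sub["t"].to_numpy(float), sub[value_col].to_numpy(float))
    return out


def build_streams(cohort, ppg_config=None) -> StreamSet:
    """Turn a synthetic (or loaded) cohort's raw streams into a StreamSet."""
    ss = StreamSet()

    hrv = cohort.watch_hrv_stream(ppg_config)
    for feat in HRV_FEATURES:
        col = f"hrv_{feat}"
        if col in hrv.columns:
            sub = hrv[np.isfinite(hrv[col])][["participant_id", "t", col]]
            ss.point[col] = (DEVICE_WATCH, "mean", _by_pid(sub, col))

    sleep = cohort.sleep
    for col in sleep.columns:
        if col.startswith("sleep_"):
            ss.last[col] = (DEVICE_RING, _by_pid(sleep, col))

    ev = cohort.events
    for kind in CALL_TYPES:
        sub = ev[ev["type"] == kind].copy()
        sub["one"] = 1.0
        ss.point[f"{kind}_count"] = (DEVICE_PHONE, "sum", _by_pid(sub, "one"))
        if kind in CALL_DURATION_TYPES:
            ss.point[f"{kind}_duration_s"] = (DEVICE_PHONE, "sum", _by_pid(sub, "duration_s"))
    for kind in ("message_incoming", "message_outgoing"):
        sub = ev[ev["type"] == kind].copy()
        sub["one"] = 1.0
        ss.point[f"{kind}_count"] = (DEVICE_PHONE, "sum", _by_pid(sub, "one"))

    app_map = load_app_category_map()
    notif = ev[ev["type"] == "notification"].copy()
    notif["category"] = notif["app_package"].map(lambda p: app_map.get(p, "Unknown"))
    notif["one"] = 1.0
    for cat in CATEGORIES:
        sub = notif[notif["category"] == cat]
        ss.point[f"notif_{cat}"] = (DEVICE_PHONE, "sum", _by_pid(sub, "one"))

    unlocks = ev[ev["type"] == "screen_unlock"].copy()
    unlocks["one"] = 1.0
    ss.point["screen_unlock_count"] = (DEVICE_PHONE, "sum", _by_pid(unlocks, "one"))
    sess = {}
    for pid, sub in ev.groupby("participant_id", sort=True):
        sess[pid] = screen_sessions(sub)
    ss.interval["screen_on_duration_s"] = (DEVICE_PHONE, sess)

    contexts = {}
    for pid, sub in cohort.gps.groupby("participant_id", sort=True):
        contexts[pid] = build_context(sub["t"].to_numpy(float),
                                      sub["lat"].to_numpy(float),
                                      sub["lon"].to_numpy(float))
    for feat in LOCATION_FEATURES:
        ss.window[feat] = (DEVICE_PHONE, contexts)
    return ss


# ---------------------------------------------------------------------------
# aggregation

def aggregate_point(t: np.ndarray, v: np.ndarray, ema_t: np.ndarray,
                    window_s: float, kind: str) -> np.ndarray:
    """Aggregate a point stream over ``[t_ema - window, t_ema)`` per EMA.

    'mean' returns NaN (missing) for empty windows; 'sum' returns the sum of
    event values, zero when no event fell in the window.
    """
    lo = np.searchsorted(t, ema_t - window_s, side="left")
    hi = np.searchsorted(t, ema_t, side="left")
    cs = np.concatenate([[0.0], np.cumsum(v)])
    total = cs[hi] - cs[lo]
    n = hi - lo
    if kind == "sum":
        return total
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, total / np.maximum(n, 1), np.nan)


def aggregate_interval(intervals: np.ndarray, ema_t: np.ndarray, window_s: float) -> np.ndarray:
    out = np.zeros(len(ema_t))
    if len(intervals) == 0:
        return out
    for i, te in enumerate(ema_t):
        a, b = te - window_s, te
        s = np.clip(intervals[:, 0], a, b)
        e = np.clip(intervals[:, 1], a, b)
        out[i] = np.maximum(e - s, 0.0).sum()
    return out


def aggregate_last(t: np.ndarray, v: np.ndarray, ema_t: np.ndarray,
                   max_lookback_s: float = MAX_SLEEP_LOOKBACK_S) -> np.ndarray:
    idx = np.searchsorted(t, ema_t, side="right") - 1
    ok = idx >= 0
    vals = np.full(len(ema_t), np.nan)
    sel = idx[ok]
    age = ema_t[ok] - t[sel]
    good = age <= max_lookback_s
    out_idx = np.flatnonzero(ok)[good]
    vals[out_idx] = v[sel[good]]
    return vals


def _candidate_values(ss: StreamSet, ema: pd.DataFrame,
                      grid_h: tuple = WINDOW_GRID_H) -> tuple[dict, dict]:
    """values[feature][window_h] -> array aligned with ema rows; 'last'
    features get a single pseudo-window keyed 'nightly'."""
    pids = ema["participant_id"].to_numpy()
    ema_t = ema["t"].to_numpy(float)
    n = len(ema)
    values: dict[str, dict] = {}
    groups = {pid: np.flatnonzero(pids == pid) for pid in np.unique(pids)}

    for name, (_, kind, data) in ss.point.items():
        values[name] = {}
        for w in grid_h:
            arr = np.full(n, np.nan if kind == "mean" else 0.0)
            for pid, rows in groups.items():
                t, v = data.get(pid, (np.empty(0), np.empty(0)))
                arr[rows] = aggregate_point(t, v, ema_t[rows], w * 3600.0, kind)
            values[name][w] = arr
    for name, (_, data) in ss.interval.items():
        values[name] = {}
        for w in grid_h:
            arr = np.zeros(n)
            for pid, rows in groups.items():
                arr[rows] = aggregate_interval(data.get(pid, np.empty((0, 2))),
                                               ema_t[rows], w * 3600.0)
            values[name][w] = arr
    for name, (_, data) in ss.last.items():
        arr = np.full(n, np.nan)
        for pid, rows in groups.items():
            t, v = data.get(pid, (np.empty(0), np.empty(0)))
            if len(t):
                arr[rows] = aggregate_last(t, v, ema_t[rows])
        values[name] = {"nightly": arr}
    if ss.window:
        loc_feats = list(ss.window)
        ctxs = next(iter(ss.window.values()))[1]
        for name in loc_feats:
            values[name] = {w: np.full(n, np.nan) for w in grid_h}
        for pid, rows in groups.items():
            ctx = ctxs.get(pid)
            if ctx is None:
                continue
            for r in rows:
                for w in grid_h:
                    feats = location_features(ctx, (ema_t[r] - w * 3600.0, ema_t[r]))
                    for name in loc_feats:
                        values[name][w][r] = feats[name]
    return values, groups


# ---------------------------------------------------------------------------
# selection, filtering, imputation, labels

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx < 1e-12 or sy < 1e-12:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


@dataclass(frozen=True)
class WindowSpec:
    feature: str
    window_hours: object  # int hours, or 'nightly' for ring summaries
    correlation: float
    flagged: bool = False


def select_windows(candidates: dict, scores: np.ndarray, train_mask: np.ndarray,
                   grid_h: tuple = WINDOW_GRID_H) -> dict[str, WindowSpec]:
    """Per feature, pick the window with the largest |Pearson r| against the
    loneliness scores over training rows; ties go to the shorter window;
    features with no computable correlation fall back to 24 h, flagged."""
    out = {}
    for name, per_w in candidates.items():
        if list(per_w) == ["nightly"]:
            r = _pearson(per_w["nightly"][train_mask], scores[train_mask])
            out[name] = WindowSpec(name, "nightly", r)
            continue
        best_w, best_r = None, -1.0
        for w in sorted(per_w):
            r = _pearson(per_w[w][train_mask], scores[train_mask])
            if np.isfinite(r) and abs(r) > best_r + 1e-15:
                best_w, best_r = w, abs(r)
        if best_w is None:
            out[name] = WindowSpec(name, DEFAULT_WINDOW_H, np.nan, flagged=True)
        else:
            out[name] = WindowSpec(name, best_w, best_r)
    return out


def filter_missing(values: dict[str, np.ndarray],
                   threshold: float = MISSING_THRESHOLD) -> tuple[dict, list]:
    """Drop features whose pooled missing fraction is strictly above the
    threshold (a column at exactly the threshold is retained)."""
    kept, dropped = {}, []
    for name, arr in values.items():
        frac = float(np.mean(~np.isfinite(arr)))
        if frac > threshold:
            dropped.append((name, frac))
        else:
            kept[name] = arr
    if values and not kept:
        raise DataError("all feature columns exceed the missingness threshold")
    return kept, dropped


def impute_neighbors(arr: np.ndarray, groups: dict, order_t: np.ndarray) -> np.ndarray:
    """Method A: mean of up to two preceding and two succeeding valid samples
    of the same participant (fewer at the edges; at least one required)."""
    out = arr.copy()
    for _, rows in groups.items():
        rows = rows[np.argsort(order_t[rows], kind="stable")]
        v = arr[rows]
        miss = np.flatnonzero(~np.isfinite(v))
        if len(miss) == 0:
            continue
        valid_idx = np.flatnonzero(np.isfinite(v))
        if len(valid_idx) == 0:
            continue
        pos = np.searchsorted(valid_idx, miss)
        for m, p in zip(miss, pos):
            before = valid_idx[max(0, p - 2):p]
            after = valid_idx[p:p + 2]
            nb = np.concatenate([before, after])
            if len(nb):
                out[rows[m]] = v[nb].mean()
    return out


def impute_participant_mean(arr: np.ndarray, groups: dict) -> np.ndarray:
    """Method B: mean of all of the participant's valid values."""
    out = arr.copy()
    for _, rows in groups.items():
        v = arr[rows]
        ok = np.isfinite(v)
        if ok.any():
            out[rows[~ok]] = v[ok].mean()
    return out


def impute(values: dict[str, np.ndarray], groups: dict, order_t: np.ndarray,
           method: str, train_mask: np.ndarray,
           flags: dict | None = None) -> dict[str, np.ndarray]:
    """Fill missing values with method 'A' (neighbours) or 'B' (participant
    mean); rows still missing (participant with no valid value) fall back to
    the pooled training mean and are flagged."""
    out = {}
    for name, arr in values.items():
        if method == "A":
            filled = impute_neighbors(arr, groups, order_t)
        elif method == "B":
            filled = impute_participant_mean(arr, groups)
        else:
            raise ValueError("method must be 'A' or 'B'")
        left = ~np.isfinite(filled)
        if left.any():
            tr = arr[train_mask]
            pooled = np.nanmean(tr) if np.isfinite(tr).any() else 0.0
            filled[left] = pooled
            if flags is not None:
                flags.setdefault("pooled_mean_fallback", []).append(name)
        out[name] = filled
    return out


def select_imputation(values: dict[str, np.ndarray], groups: dict, order_t: np.ndarray,
                      scores: np.ndarray, train_mask: np.ndarray) -> tuple[str, dict]:
    """Compare |r| with the scores under methods A and B per feature (training
    rows only); the method winning the majority of features is used for all
    features.  Ties - per feature and in the majority count - go to B."""
    stats = {}
    for name, arr in values.items():
        a = impute_neighbors(arr, groups, order_t)
        b = impute_participant_mean(arr, groups)
        ra = _pearson(a[train_mask], scores[train_mask])
        rb = _pearson(b[train_mask], scores[train_mask])
        stats[name] = (ra, rb)
    wins_a = sum(1 for ra, rb in stats.values()
                 if np.isfinite(ra) and (not np.isfinite(rb) or abs(ra) > abs(rb)))
    wins_b = len(stats) - wins_a
    return ("B" if wins_b >= wins_a else "A"), stats


def make_labels(ema: pd.DataFrame, mode: str = "full",
                train_mask: np.ndarray | None = None,
                min_scores: int = 4) -> tuple[pd.Series, list[str]]:
    """Per-participant median-split labels: lonely iff score > median.

    ``mode='full'`` computes each participant's median over their whole score
    series; ``mode='train'`` restricts to training rows.  Participants whose
    labels collapse to one class (constant scores) or with fewer than
    ``min_scores`` responses are excluded with a warning.
    """
    labels = pd.Series(np.zeros(len(ema), dtype=int), index=ema.index)
    excluded = []
    for pid, sub in ema.groupby("participant_id", sort=True):
        scores = sub["score"].to_numpy(float)
        if mode == "train":
            if train_mask is None:
                raise ValueError("train_mask required for mode='train'")
            base = scores[train_mask[ema.index.get_indexer(sub.index)]]
        else:
            base = scores
        if len(scores) < min_scores or len(base) == 0:
            excluded.append(pid)
            continue
        m = np.median(base)
        lab = (scores > m).astype(int)
        if lab.min() == lab.max():
            excluded.append(pid)
            continue
        labels.loc[sub.index] = lab
    if excluded:
        warnings.warn(f"participants excluded from modeling (degenerate labels): {excluded}")
    return labels, excluded


def znormalize_split(df: pd.DataFrame, feature_cols: list[str], train_index: np.ndarray,
                     apply_index: np.ndarray | None = None,
                     eps: float = 1e-8) -> tuple[pd.DataFrame, dict]:
    """Z-normalize features per participant using that participant's training
    rows only; constant training columns get SD 1 and a flag.  A participant
    appearing outside training but never inside it is an error."""
    flags: dict = {}
    out = df.copy()
    apply_index = df.index.to_numpy() if apply_index is None else apply_index
    train_pids = set(df.loc[train_index, "participant_id"])
    apply_pids = set(df.loc[apply_index, "participant_id"])
    missing = apply_pids - train_pids
    if missing:
        raise DataError(f"participants absent from training rows: {sorted(missing)}")
    for pid in sorted(apply_pids):
        tr = df.loc[train_index][df.loc[train_index, "participant_id"] == pid]
        rows = df.loc[apply_index][df.loc[apply_index, "participant_id"] == pid].index
        mu = tr[feature_cols].mean(axis=0)
        sd = tr[feature_cols].std(axis=0, ddof=0)
        degen = sd < eps
        if degen.any():
            flags.setdefault("constant_training_feature", {})[pid] = list(sd.index[degen])
        sd = sd.where(~degen, 1.0)
        out.loc[rows, feature_cols] = (df.loc[rows, feature_cols] - mu) / sd
    return out, flags


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class FeatureTable:
    """The modeling table: one row per retained EMA, imputed feature columns
    with device-of-origin tags, the 0-100 score and the binary label."""

    df: pd.DataFrame
    feature_cols: list[str]
    device_of: dict[str, str]
    imputation_method: str

    def subset(self, devices) -> "FeatureTable":
        cols = [c for c in self.feature_cols if self.device_of[c] in set(devices)]
        keep = ["participant_id", "t", "score", "label"] + cols
        return FeatureTable(self.df[keep].copy(), cols,
                            {c: self.device_of[c] for c in cols}, self.imputation_method)


@dataclass
class Assembly:
    """Intermediate assembly state; ``materialize`` produces modeling tables
    (optionally restricted to a device subset, re-running the imputation
    method vote on the restricted feature set)."""

    ema: pd.DataFrame
    values: dict[str, np.ndarray]
    groups: dict
    device_of: dict[str, str]
    window_spec: dict[str, WindowSpec]
    dropped: list
    imputation_stats: dict
    imputation_method: str
    train_mask: np.ndarray
    excluded_participants: list
    flags: dict = field(default_factory=dict)

    def materialize(self, devices=None) -> FeatureTable:
        devices = set(devices) if devices is not None else set(ALL_DEVICES)
        cols = [c for c in self.values if self.device_of[c] in devices]
        if not cols:
            raise DataError(f"no feature columns for device subset {sorted(devices)}")
        stats = {c: self.imputation_stats[c] for c in cols}
        wins_a = sum(1 for ra, rb in stats.values()
                     if np.isfinite(ra) and (not np.isfinite(rb) or abs(ra) > abs(rb)))
        method = "B" if (len(stats) - wins_a) >= wins_a else "A"
        order_t = self.ema["t"].to_numpy(float)
        filled = impute({c: self.values[c] for c in cols}, self.groups, order_t,
                        method, self.train_mask, self.flags)
        df = self.ema[["participant_id", "t", "score", "label"]].copy()
        for c in cols:
            df[c] = filled[c]
        return FeatureTable(df.reset_index(drop=True), cols,
                            {c: self.device_of[c] for c in cols}, method)


def training_row_mask(ema: pd.DataFrame) -> np.ndarray:
    """Earliest 50 % of each participant's EMAs (ceil goes to training)."""
    mask = np.zeros(len(ema), dtype=bool)
    for _, sub in ema.groupby("participant_id", sort=False):
        order = sub["t"].sort_values(kind="stable").index
        n_tr = int(np.ceil(len(order) / 2))
        mask[ema.index.get_indexer(order[:n_tr])] = True
    return mask


def assemble_features(streams: StreamSet, ema: pd.DataFrame,
                      grid_h: tuple = WINDOW_GRID_H, median_mode: str = "full",
                      missing_threshold: float = MISSING_THRESHOLD) -> Assembly:
    """Run the full assembly: aggregation, window selection, missingness
    filtering, imputation-method selection and labeling."""
    ema = ema.sort_values(["participant_id", "t"], kind="stable").reset_index(drop=True)
    train_mask = training_row_mask(ema)
    labels, excluded = make_labels(ema, median_mode, train_mask)
    ema = ema.assign(label=labels)
    keep = ~ema["participant_id"].isin(excluded)
    ema = ema[keep].reset_index(drop=True)
    train_mask = train_mask[keep.to_numpy()]

    candidates, groups = _candidate_values(streams, ema, grid_h)
    scores = ema["score"].to_numpy(float)
    spec = select_windows(candidates, scores, train_mask, grid_h)
    chosen = {name: candidates[name][spec[name].window_hours]
              if spec[name].window_hours in candidates[name]
              else candidates[name][min(candidates[name], key=lambda w: abs(w - DEFAULT_WINDOW_H))]
              for name in candidates}
    kept, dropped = filter_missing(chosen, missing_threshold)
    order_t = ema["t"].to_numpy(float)
    method, stats = select_imputation(kept, groups, order_t, scores, train_mask)
    devices = streams.devices()
    return Assembly(ema=ema, values=kept, groups=groups,
                    device_of={c: devices[c] for c in kept},
                    window_spec={c: spec[c] for c in kept},
                    dropped=dropped, imputation_stats=stats, imputation_method=method,
                    train_mask=train_mask, excluded_participants=excluded)
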