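"""The ten GPS mobility features, computed over arbitrary look-back windows.

A :class:`LocationContext` pre-computes, once per participant, everything the
windowed queries need (derived speeds, stay points, places, the
stay-collapsed travel path), so that evaluating the feature set for
thousands of (EMA, candidate-window) pairs stays cheap.

Feature notes
-------------
* ``travel_distance_km`` is the haversine length of the *stay-collapsed*
  trajectory (each stay replaced by its centroid).  A raw fix-to-fix path sum
  is dominated by GPS jitter while dwelling (hundreds of spurious metres per
  stationary hour) and systematically overestimates travel.
* the four "(>= 2 places)" features are reported missing (NaN) for windows
  in which fewer than two places were visited.
* speeds are taken from the sensor when present, otherwise finite-difference
  haversine speed; legs with a gap > 10 min are excluded from speed stats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geo import haversine_m
from .places import Place, Stay, detect_home, detect_stays, merge_stays

LOCATION_FEATURES = [
    "lat_variance", "speed_variance", "speed_mean", "number_of_places",
    "home_duration_min", "outdoor_duration_min", "outdoor_stay_mean_min",
    "outdoor_stay_sd_min", "longest_nonhome_stay_min", "travel_distance_km",
]

GAP_RULE_S = 600.0  # legs longer than this are excluded from speed statistics


@dataclass
class LocationContext:
    """Pre-computed per-participant mobility state for windowed queries."""

    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    home: Place
    stays: list[Stay]
    places: list[Place]
    speeds: np.ndarray          # per-leg speed (m/s) at leg start fix, NaN if gap rule
    at_home: np.ndarray         # per-fix, within home radius
    path_t: np.ndarray          # stay-collapsed path timestamps
    path_cumdist: np.ndarray    # cumulative haversine metres along that path
    radius_m: float
    min_dwell_s: float


def build_context(t: np.ndarray, lat: np.ndarray, lon: np.ndarray,
                  home: Place | None = None, speed: np.ndarray | None = None,
                  radius_m: float = 150.0, min_dwell_s: float = 600.0) -> LocationContext:
    """Prepare a participant's GPS trace for windowed feature extraction."""
    order = np.argsort(t, kind="stable")
    t, lat, lon = t[order], lat[order], lon[order]
    if home is None:
        home = detect_home(t, lat, lon, radius_m=radius_m)
    stays = detect_stays(t, lat, lon, radius_m, min_dwell_s)
    places = merge_stays(stays, radius_m)
    for p in places:
        if haversine_m(p.lat, p.lon, home.lat, home.lon) <= radius_m:
            p.is_home = True

    dt = np.diff(t)
    leg = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    with np.errstate(invalid="ignore", divide="ignore"):
        deriv = np.where(dt > 0, leg / np.maximum(dt, 1e-9), np.nan)
    speeds = speed[:-1].astype(float) if speed is not None else deriv
    speeds = np.where(dt <= GAP_RULE_S, speeds, np.nan)

    at_home = haversine_m(lat, lon, home.lat, home.lon) <= radius_m

    # stay-collapsed path: transit fixes as-is, stays as centroid at entry/exit
    in_stay = np.zeros(len(t), dtype=bool)
    pts_t, pts_lat, pts_lon = [], [], []
    for s in stays:
        in_stay[s.i0:s.i1 + 1] = True
    i = 0
    si = 0
    while i < len(t):
        if si < len(stays) and stays[si].i0 == i:
            s = stays[si]
            pts_t += [s.start, s.end]
            pts_lat += [s.lat, s.lat]
            pts_lon += [s.lon, s.lon]
            i = s.i1 + 1
            si += 1
        else:
            pts_t.append(t[i])
            pts_lat.append(lat[i])
            pts_lon.append(lon[i])
            i += 1
    pt = np.array(pts_t)
    plat = np.array(pts_lat)
    plon = np.array(pts_lon)
    legs = haversine_m(plat[:-1], plon[:-1], plat[1:], plon[1:]) if len(pt) > 1 else np.empty(0)
    cum = np.concatenate([[0.0], np.cumsum(legs)])
    return LocationContext(t, lat, lon, home, stays, places, speeds, at_home,
                           pt, cum, radius_m, min_dwell_s)


def _clip_dur(iv: tuple[float, float], a: float, b: float) -> float:
    return max(0.0, min(iv[1], b) - max(iv[0], a))


def location_features(ctx: LocationContext, window: tuple[float, float]) -> dict[str, float]:
    """The ten mobility features for the window ``[a, b)``."""
    a, b = window
    out = {k: np.nan for k in LOCATION_FEATURES}
    i0, i1 = np.searchsorted(ctx.t, (a, b))
    if i1 <= i0:
        return out  # no fixes in window -> all missing

    lat = ctx.lat[i0:i1]
    out["lat_variance"] = float(np.var(lat))
    sp = ctx.speeds[i0:min(i1, len(ctx.speeds))]
    sp = sp[np.isfinite(sp)]
    if len(sp):
        out["speed_mean"] = float(sp.mean())
        out["speed_variance"] = float(np.var(sp))

    # time coverage: per-fix forward intervals clipped to the window
    t_seg = ctx.t[i0:i1]
    nxt = np.empty_like(t_seg)
    nxt[:-1] = t_seg[1:]
    nxt[-1] = ctx.t[i1] if i1 < len(ctx.t) else t_seg[-1]
    durs = np.clip(np.minimum(nxt, b) - t_seg, 0.0, None)
    home_s = float(durs[ctx.at_home[i0:i1]].sum())
    covered = float(durs.sum())
    out["home_duration_min"] = home_s / 60.0
    out["outdoor_duration_min"] = (covered - home_s) / 60.0

    # places visited in the window
    visited: dict[int, list[float]] = {}
    nonhome_stays: list[float] = []
    for s in ctx.stays:
        d = _clip_dur((s.start, s.end), a, b)
        if d > 0:
            visited.setdefault(s.place, []).append(d)
            if not ctx.places[s.place].is_home:
                nonhome_stays.append(d)
    n_places = len(visited)
    out["number_of_places"] = float(n_places)

    if n_places >= 2:
        if nonhome_stays:
            arr = np.array(nonhome_stays) / 60.0
            out["outdoor_stay_mean_min"] = float(arr.mean())
            out["outdoor_stay_sd_min"] = float(np.std(arr))
            out["longest_nonhome_stay_min"] = float(arr.max())
        d0, d1 = np.interp([a, b], ctx.path_t, ctx.path_cumdist)
        out["travel_distance_km"] = float(d1 - d0) / 1000.0
    return out
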