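"""Synthetic GPS day traces: a home anchor, planted place visits, transit legs.

Geometry is an abstract plane with lat/lon semantics (no real map); distances
follow the haversine metric so downstream mobility features behave exactly as
they would on real coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..behavior.geo import haversine_m

DAY_S = 86400.0


@dataclass
class Visit:
    place_idx: int
    start: float  # seconds from day start
    end: float


@dataclass
class LocationDayTruth:
    """Ground truth for one simulated participant-day."""

    visits: list[Visit] = field(default_factory=list)
    travel_m: float = 0.0  # haversine length of the true (noise-free) path


def _dest(lat: float, lon: float, bearing_rad: float, dist_m: float) -> tuple[float, float]:
    dlat = dist_m * np.cos(bearing_rad) / 111320.0
    dlon = dist_m * np.sin(bearing_rad) / (111320.0 * np.cos(np.radians(lat)))
    return lat + dlat, lon + dlon


def simulate_location_day(home: tuple[float, float], places: list[tuple[float, float]],
                          mobility_level: float, rng: np.random.Generator,
                          n_visits: int | None = None,
                          dwell_range_min: tuple[float, float] = (40.0, 120.0),
                          fix_interval_moving_s: float = 120.0,
                          fix_interval_still_s: float = 300.0,
                          gps_jitter_m: float = 10.0,
                          speed_ms: float = 6.0,
                          day_offset_s: float = 0.0):
    """Simulate one day of GPS fixes.

    The participant is home during 00:00-08:00 and after the last visit;
    ``mobility_level`` in [0, inf) scales the expected number of visited
    places (0 means an all-home day).  Fixes are sampled sparsely (5 min)
    while stationary and densely (2 min) in transit, with isotropic Gaussian
    jitter of ``gps_jitter_m``.

    Returns ``(t, lat, lon, truth)`` where ``t`` is in seconds from the
    cohort epoch (``day_offset_s`` + within-day second).
    """
    if len(places) < 1:
        raise ValueError("need at least one candidate place")
    if n_visits is None:
        n_visits = int(rng.poisson(mobility_level)) if mobility_level > 0 else 0
    n_visits = min(n_visits, 6)

    truth = LocationDayTruth()
    # itinerary: (lat, lon, start_s, end_s, moving) legs covering the day
    path_t, path_lat, path_lon = [], [], []  # waypoints of the true path

    def add_waypoint(ts, la, lo):
        path_t.append(ts)
        path_lat.append(la)
        path_lon.append(lo)

    cur = home
    t_cur = 0.0
    add_waypoint(0.0, *home)
    first_leave = 8 * 3600.0 + rng.uniform(0, 3600.0)
    t_cur = first_leave
    add_waypoint(t_cur, *home)
    order = rng.permutation(len(places))[:n_visits]
    for k in order:
        dest = places[int(k)]
        d = haversine_m(cur[0], cur[1], dest[0], dest[1])
        travel = max(d / speed_ms, 60.0)
        t_arr = t_cur + travel
        dwell = rng.uniform(*dwell_range_min) * 60.0
        t_dep = t_arr + dwell
        if t_dep > 22.5 * 3600.0:
            break
        add_waypoint(t_arr, *dest)
        add_waypoint(t_dep, *dest)
        truth.visits.append(Visit(int(k), t_arr, t_dep))
        cur = dest
        t_cur = t_dep
    if cur != home:
        d = haversine_m(cur[0], cur[1], home[0], home[1])
        t_back = t_cur + max(d / speed_ms, 60.0)
        add_waypoint(t_back, *home)
        cur = home
        t_cur = t_back
    add_waypoint(DAY_S, *home)

    path_t = np.array(path_t)
    path_lat = np.array(path_lat)
    path_lon = np.array(path_lon)
    truth.travel_m = float(haversine_m(path_lat[:-1], path_lon[:-1],
                                       path_lat[1:], path_lon[1:]).sum())

    # sample fixes: dense while moving, sparse while still
    seg_moving = haversine_m(path_lat[:-1], path_lon[:-1], path_lat[1:], path_lon[1:]) > 1.0
    ts = []
    for i in range(len(path_t) - 1):
        step = fix_interval_moving_s if seg_moving[i] else fix_interval_still_s
        ts.append(np.arange(path_t[i], path_t[i + 1], step))
    ts = np.concatenate(ts) if ts else np.empty(0)
    ts += rng.uniform(-5, 5, size=len(ts))
    ts = np.sort(np.clip(ts, 0, DAY_S - 1))
    ts = ts[np.concatenate([[True], np.diff(ts) > 1.0])]

    lat = np.interp(ts, path_t, path_lat)
    lon = np.interp(ts, path_t, path_lon)
    jit = rng.normal(0.0, gps_jitter_m, size=(len(ts), 2))
    lat = lat + jit[:, 0] / 111320.0
    lon = lon + jit[:, 1] / (111320.0 * np.cos(np.radians(home[0])))
    return ts + day_offset_s, lat, lon, truth


def make_places(home: tuple[float, float], n: int, rng: np.random.Generator,
                dist_range_m: tuple[float, float] = (600.0, 3000.0)) -> list[tuple[float, float]]:
    """Place candidate centroids around a home anchor."""
    out = []
    for _ in range(n):
        bearing = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(*dist_range_m)
        out.append(_dest(home[0], home[1], bearing, dist))
    return out
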