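"""Stay-point extraction, significant places, and home detection from GPS.

Stay points follow the classic scan: a maximal run of consecutive fixes that
all remain within ``radius`` of the anchor fix and span at least
``min_dwell`` seconds.  Stays are merged into places when their centroids lie
within ``radius`` of each other; home is the place with the greatest total
dwell during the night window (00:00-06:00 local by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geo import haversine_m, local_xy
from ..errors import DataError

DAY_S = 86400.0


@dataclass
class Stay:
    start: float
    end: float
    lat: float
    lon: float
    i0: int  # first/last fix index of the stay
    i1: int
    place: int = -1  # filled by merge_stays

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class Place:
    lat: float
    lon: float
    is_home: bool = False
    visits: list[tuple[float, float]] = field(default_factory=list)

    @property
    def total_dwell(self) -> float:
        return float(sum(e - s for s, e in self.visits))


def detect_stays(t: np.ndarray, lat: np.ndarray, lon: np.ndarray,
                 radius_m: float = 150.0, min_dwell_s: float = 600.0) -> list[Stay]:
    """Extract stay points from a time-ordered fix sequence."""
    n = len(t)
    if n == 0:
        return []
    x, y = local_xy(lat, lon)
    stays: list[Stay] = []
    i = 0
    while i < n - 1:
        # chunked look-ahead for the first fix leaving the anchor's radius
        j = n - 1  # last fix still within radius
        lo = i + 1
        while lo < n:
            hi = min(lo + 256, n)
            d = np.hypot(x[lo:hi] - x[i], y[lo:hi] - y[i])
            far = np.nonzero(d > radius_m)[0]
            if len(far):
                j = lo + far[0] - 1
                break
            lo = hi
        if t[j] - t[i] >= min_dwell_s:
            sl = slice(i, j + 1)
            stays.append(Stay(t[i], t[j], float(lat[sl].mean()), float(lon[sl].mean()), i, j))
            i = j + 1
        else:
            i += 1
    return stays


def merge_stays(stays: list[Stay], radius_m: float = 150.0) -> list[Place]:
    """Greedily merge stays into places by centroid distance."""
    places: list[Place] = []
    for s in stays:
        for k, p in enumerate(places):
            if haversine_m(s.lat, s.lon, p.lat, p.lon) <= radius_m:
                w = p.total_dwell
                tot = w + s.duration
                if tot > 0:
                    p.lat = (p.lat * w + s.lat * s.duration) / tot
                    p.lon = (p.lon * w + s.lon * s.duration) / tot
                p.visits.append((s.start, s.end))
                s.place = k
                break
        else:
            s.place = len(places)
            places.append(Place(s.lat, s.lon, visits=[(s.start, s.end)]))
    return places


def detect_places(t: np.ndarray, lat: np.ndarray, lon: np.ndarray,
                  window: tuple[float, float] | None = None,
                  radius_m: float = 150.0, min_dwell_s: float = 600.0) -> list[Place]:
    """Stay-point places visited inside ``window`` (whole trace if None)."""
    if window is not None:
        a, b = window
        keep = (t >= a) & (t < b)
        t, lat, lon = t[keep], lat[keep], lon[keep]
    stays = detect_stays(t, lat, lon, radius_m, min_dwell_s)
    return merge_stays(stays, radius_m)


def detect_home(t: np.ndarray, lat: np.ndarray, lon: np.ndarray,
                night_window: tuple[float, float] = (0.0, 6.0),
                radius_m: float = 150.0) -> Place:
    """Home = densest night-time cluster of fixes.

    ``night_window`` is in local hours; fixes whose time of day falls inside
    it are greedily clustered (within ``radius_m`` of the running centroid)
    and the cluster with the greatest night dwell wins.  Raises
    :class:`DataError` when fewer than 3 distinct nights have fixes.
    """
    hours = (t % DAY_S) / 3600.0
    night = (hours >= night_window[0]) & (hours < night_window[1])
    if not night.any():
        raise DataError("no night-time fixes; cannot locate home")
    nt, nlat, nlon = t[night], lat[night], lon[night]
    if len(np.unique((nt // DAY_S).astype(int))) < 3:
        raise DataError("fewer than 3 nights with fixes; cannot locate home")

    cl_lat: list[float] = []
    cl_lon: list[float] = []
    cl_n: list[int] = []
    assign = np.empty(len(nt), dtype=int)
    for i in range(len(nt)):
        for k in range(len(cl_lat)):
            if haversine_m(nlat[i], nlon[i], cl_lat[k], cl_lon[k]) <= radius_m:
                cl_lat[k] = (cl_lat[k] * cl_n[k] + nlat[i]) / (cl_n[k] + 1)
                cl_lon[k] = (cl_lon[k] * cl_n[k] + nlon[i]) / (cl_n[k] + 1)
                cl_n[k] += 1
                assign[i] = k
                break
        else:
            assign[i] = len(cl_lat)
            cl_lat.append(float(nlat[i]))
            cl_lon.append(float(nlon[i]))
            cl_n.append(1)
    # dwell per cluster: sum of inter-fix gaps (capped at 15 min) per night fix
    gaps = np.minimum(np.diff(nt, append=nt[-1] + 300.0), 900.0)
    dwell = np.zeros(len(cl_lat))
    np.add.at(dwell, assign, gaps)
    best = int(np.argmax(dwell))
    return Place(cl_lat[best], cl_lon[best], is_home=True)
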