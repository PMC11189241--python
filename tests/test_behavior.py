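"""Behavioral features: home/places, mobility features, phone logs."""

import numpy as np
import pandas as pd
import pytest

from lonesense.behavior import (CATEGORIES, build_context, comm_features,
                                detect_home, detect_places, detect_stays,
                                haversine_m, load_app_category_map,
                                location_features, notification_features,
                                screen_features, screen_sessions)
from lonesense.errors import DataError

HOME = (33.70, -117.80)
DAY = 86400.0


def _fixes(specs, interval=120.0):
    """specs: list of (start_s, end_s, lat, lon) dwells; returns t, lat, lon."""
    t, la, lo = [], [], []
    for a, b, lat, lon in specs:
        tt = np.arange(a, b, interval)
        t.append(tt)
        la.append(np.full(len(tt), lat))
        lo.append(np.full(len(tt), lon))
    t = np.concatenate(t)
    order = np.argsort(t)
    return t[order], np.concatenate(la)[order], np.concatenate(lo)[order]


def _offset(lat, lon, north_m=0.0, east_m=0.0):
    return (lat + north_m / 110540.0,
            lon + east_m / (111320.0 * np.cos(np.radians(lat))))


class TestHomeDetection:
    def test_single_night_location_is_home(self):
        specs = [(d * DAY, d * DAY + 8 * 3600, *HOME) for d in range(4)]
        t, la, lo = _fixes(specs)
        h = detect_home(t, la, lo)
        assert haversine_m(h.lat, h.lon, *HOME) < 1.0

    def test_dominant_night_cluster_wins(self):
        other = _offset(*HOME, north_m=2000)
        specs = []
        for d in range(5):  # 5 h/night at home, 1 h at the other place
            specs.append((d * DAY, d * DAY + 5 * 3600, *HOME))
            specs.append((d * DAY + 5 * 3600, d * DAY + 6 * 3600, *other))
        t, la, lo = _fixes(specs)
        h = detect_home(t, la, lo)
        assert haversine_m(h.lat, h.lon, *HOME) < 50.0

    def test_no_night_fixes_errors(self):
        t, la, lo = _fixes([(12 * 3600, 14 * 3600, *HOME)])
        with pytest.raises(DataError):
            detect_home(t, la, lo)

    def test_too_few_nights_errors(self):
        t, la, lo = _fixes([(0, 6 * 3600, *HOME), (DAY, DAY + 6 * 3600, *HOME)])
        with pytest.raises(DataError):
            detect_home(t, la, lo)


class TestPlaces:
    def test_stationary_day_single_place(self):
        t, la, lo = _fixes([(0, DAY, *HOME)])
        places = detect_places(t, la, lo)
        assert len(places) == 1

    def test_planted_places_plus_home(self):
        p1 = _offset(*HOME, north_m=1500)
        p2 = _offset(*HOME, east_m=2000)
        p3 = _offset(*HOME, north_m=-1800)
        specs = [(0, 9 * 3600, *HOME)]
        for i, p in enumerate((p1, p2, p3)):
            a = (9 + 2 * i) * 3600
            specs.append((a, a + 3600, *p))  # 1-h dwells
        specs.append((16 * 3600, DAY, *HOME))
        t, la, lo = _fixes(specs)
        assert len(detect_places(t, la, lo)) == 4

    def test_brief_passes_do_not_create_places(self):
        p1 = _offset(*HOME, north_m=1500)
        specs = [(0, 9 * 3600, *HOME),
                 (9 * 3600, 9 * 3600 + 300, *p1),  # 5 min < min_dwell
                 (10 * 3600, DAY, *HOME)]
        t, la, lo = _fixes(specs)
        assert len(detect_places(t, la, lo)) == 1

    def test_stay_merging_within_radius(self):
        # two dwells 60 m apart, separated by an excursion beyond the stay
        # radius: two stay points, merged into one place
        near = _offset(*HOME, north_m=60)
        far = _offset(*HOME, north_m=600)
        t, la, lo = _fixes([(0, 3600, *HOME), (3700, 3900, *far),
                            (4000, 2 * 3600 + 4000, *near)])
        stays = detect_stays(t, la, lo)
        assert len(stays) == 2
        from lonesense.behavior import merge_stays
        assert len(merge_stays(stays)) == 1


class TestLocationFeatures:
    def _context(self, specs, home=HOME, interval=120.0):
        t, la, lo = _fixes(specs, interval)
        from lonesense.behavior.places import Place
        return build_context(t, la, lo, home=Place(home[0], home[1], is_home=True))

    def test_all_home_window(self):
        ctx = self._context([(0, DAY, *HOME)])
        f = location_features(ctx, (0.0, DAY))
        assert f["home_duration_min"] == pytest.approx(1440, abs=3)
        assert f["outdoor_duration_min"] == pytest.approx(0, abs=1e-9)
        assert f["number_of_places"] == 1
        assert np.isnan(f["travel_distance_km"])  # < 2 places

    def test_haversine_closed_form(self):
        d = haversine_m(33.0, -117.0, 33.01, -117.0)
        assert d == pytest.approx(1112.0, rel=0.01)

    def test_home_plus_outdoor_equals_covered(self):
        p1 = _offset(*HOME, north_m=1500)
        ctx = self._context([(0, 10 * 3600, *HOME), (10 * 3600, 12 * 3600, *p1),
                             (12 * 3600, DAY, *HOME)])
        f = location_features(ctx, (0.0, DAY))
        covered = ctx.t[-1] - ctx.t[0]
        total = (f["home_duration_min"] + f["outdoor_duration_min"]) * 60
        assert total == pytest.approx(covered, abs=240)

    def test_two_places_enables_outdoor_stats(self):
        p1 = _offset(*HOME, north_m=1500)
        ctx = self._context([(0, 10 * 3600, *HOME), (10 * 3600, 12 * 3600, *p1),
                             (12 * 3600, DAY, *HOME)])
        f = location_features(ctx, (0.0, DAY))
        assert f["number_of_places"] == 2
        assert f["longest_nonhome_stay_min"] == pytest.approx(120, abs=5)
        assert f["outdoor_stay_mean_min"] == pytest.approx(120, abs=5)
        # collapsed-path travel: 2 x 1.5 km legs
        assert f["travel_distance_km"] == pytest.approx(3.0, rel=0.05)

    def test_empty_window_all_missing(self):
        ctx = self._context([(0, DAY, *HOME)])
        f = location_features(ctx, (2 * DAY, 3 * DAY))
        assert all(np.isnan(v) for v in f.values())

    def test_null_mobility_lat_variance_bounded_by_jitter(self, rng):
        jitter = 10.0
        t = np.arange(0, DAY, 120.0)
        la = HOME[0] + rng.normal(0, jitter / 110540.0, len(t))
        lo = np.full(len(t), HOME[1])
        from lonesense.behavior.places import Place
        ctx = build_context(t, la, lo, home=Place(*HOME, is_home=True))
        f = location_features(ctx, (0.0, DAY))
        assert f["lat_variance"] <= 2.0 * (jitter / 110540.0) ** 2


def _log(rows):
    return pd.DataFrame(rows, columns=["participant_id", "t", "type",
                                       "duration_s", "app_package"])


class TestCommFeatures:
    def test_empty_log_zeros(self):
        f = comm_features(_log([]), (0, 3600))
        assert all(v == 0 for v in f.values())

    def test_call_counts_and_durations(self):
        log = _log([("p", 10, "call_incoming", 60.0, ""),
                    ("p", 20, "call_incoming", 30.0, ""),
                    ("p", 30, "call_voicemail", 12.0, "")])
        f = comm_features(log, (0, 3600))
        assert f["call_incoming_count"] == 2
        assert f["call_incoming_duration_s"] == 90.0
        assert f["call_voicemail_count"] == 1

    def test_window_counts_conserve_day_total(self, rng):
        t = rng.uniform(0, DAY, 200)
        log = _log([("p", tt, "message_incoming", 0.0, "") for tt in t])
        total = sum(comm_features(log, (a, a + 6 * 3600))["message_incoming_count"]
                    for a in range(0, int(DAY), 6 * 3600))
        assert total == 200


class TestNotificationFeatures:
    def test_category_map_shipped_examples(self):
        log = _log([("p", i, "notification", 0.0, pkg) for i, pkg in
                    enumerate(["whatsapp", "whatsapp", "whatsapp", "discord"])])
        f = notification_features(log, (0, 3600))
        assert f["notif_Communication"] == 4

    def test_unmapped_package_counts_as_unknown(self):
        log = _log([("p", 1, "notification", 0.0, "com.example.foo")])
        f = notification_features(log, (0, 3600))
        assert f["notif_Unknown"] == 1

    def test_partition_identity(self, rng):
        pkgs = list(load_app_category_map()) + ["com.example.bar"]
        rows = [("p", i, "notification", 0.0, pkgs[int(rng.integers(len(pkgs)))])
                for i in range(137)]
        f = notification_features(_log(rows), (0, 3600))
        assert sum(f.values()) == 137
        assert set(f) == {f"notif_{c}" for c in CATEGORIES}


class TestScreenFeatures:
    def test_simple_session(self):
        log = _log([("p", 600, "screen_unlock", 0.0, ""),
                    ("p", 900, "screen_lock", 0.0, "")])
        f = screen_features(log, (0, 3600))
        assert f["screen_unlock_count"] == 1
        assert f["screen_on_duration_s"] == 300.0

    def test_unpaired_unlock_truncated_at_window_edge(self):
        log = _log([("p", 3000, "screen_unlock", 0.0, "")])
        f = screen_features(log, (0, 3600))
        assert f["screen_on_duration_s"] == 600.0

    def test_nested_unlocks_sanitised(self, rng):
        rows = []
        for i in range(50):  # duplicate unlocks and locks in random order
            rows.append(("p", 100 * i, "screen_unlock", 0.0, ""))
            rows.append(("p", 100 * i + 30, "screen_unlock", 0.0, ""))
            rows.append(("p", 100 * i + 60, "screen_lock", 0.0, ""))
            rows.append(("p", 100 * i + 61, "screen_lock", 0.0, ""))
        f = screen_features(_log(rows), (0, 5000))
        assert f["screen_on_duration_s"] <= 5000
        sess = screen_sessions(_log(rows))
        assert (np.diff(sess.ravel()) >= 0).all()  # disjoint, ordered
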