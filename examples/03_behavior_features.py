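"""Extract mobility and phone-usage features from a simulated week.

Detects the home location from night-time GPS, finds significant places,
computes the ten mobility features over a one-day window, and counts
calls/notifications/screen use from the event log.
"""

import numpy as np

from lonesense.behavior import (build_context, comm_features, detect_home,
                                haversine_m, location_features,
                                notification_features, screen_features)
from lonesense.synth import (default_category_mix, make_places,
                             simulate_events_day, simulate_location_day)

rng = np.random.default_rng(11)
home = (33.70, -117.80)
places = make_places(home, 3, rng)

ts, las, lns = [], [], []
for d in range(7):
    t, la, lo, _ = simulate_location_day(home, places, 2.0, rng, day_offset_s=d * 86400)
    ts.append(t)
    las.append(la)
    lns.append(lo)
t = np.concatenate(ts)
la = np.concatenate(las)
lo = np.concatenate(lns)

h = detect_home(t, la, lo)
print(f"home detected {haversine_m(h.lat, h.lon, *home):.1f} m from the planted anchor")

ctx = build_context(t, la, lo, home=h)
f = location_features(ctx, (86400.0, 2 * 86400.0))  # day 2
print("day-2 mobility features:")
for k, v in f.items():
    print(f"  {k:26s} {v:10.3f}" if np.isfinite(v) else f"  {k:26s}    missing")

log = simulate_events_day(0.3, default_category_mix(), rng)
day = (0.0, 86400.0)
comm = comm_features(log, day)
print(f"calls in/out: {comm['call_incoming_count']:.0f}/{comm['call_outgoing_count']:.0f}, "
      f"messages in/out: {comm['message_incoming_count']:.0f}/{comm['message_outgoing_count']:.0f}")
notif = notification_features(log, day)
top = sorted(notif.items(), key=lambda kv: -kv[1])[:3]
print("top notification categories:", ", ".join(f"{k[6:]} ({v:.0f})" for k, v in top))
scr = screen_features(log, day)
print(f"screen: {scr['screen_unlock_count']:.0f} unlocks, "
      f"{scr['screen_on_duration_s'] / 60:.0f} min on")
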