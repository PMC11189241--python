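"""Phone-log features: calls, messages, notification categories, screen use.

The notification taxonomy is the 18-category scheme used for wrist/phone
digital-phenotyping studies (Productivity ... Tools, plus an ``Unknown``
bucket); a small app-to-category map with three example apps per category
ships with the package and unmapped packages fall back to ``Unknown``.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

CATEGORIES = [
    "Productivity", "Photography", "Communication", "Lifestyle",
    "Auto & Vehicles", "Travel & Local", "Education", "Finance",
    "Video Players & Editors", "Social", "Books & Reference", "Shopping",
    "Health & Fitness", "Entertainment", "Business", "Music & Audio",
    "Tools", "Unknown",
]

CALL_TYPES = ["call_incoming", "call_outgoing", "call_missed", "call_voicemail"]
#: call categories with a meaningful duration sum (missed calls have none)
CALL_DURATION_TYPES = ["call_incoming", "call_outgoing", "call_voicemail"]


def load_app_category_map() -> dict[str, str]:
    """The shipped app-package -> category map."""
    with resources.files("lonesense.data").joinpath("app_categories.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["app_package"], df["category"]))


def _example_apps() -> dict[str, list[str]]:
    apps: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for pkg, cat in load_app_category_map().items():
        apps[cat].append(pkg)
    return apps


EXAMPLE_APPS = _example_apps()


def _in_window(log: pd.DataFrame, window: tuple[float, float]) -> pd.DataFrame:
    a, b = window
    return log[(log["t"] >= a) & (log["t"] < b)]


def comm_features(log: pd.DataFrame, window: tuple[float, float]) -> dict[str, float]:
    """Call counts/duration sums per category and message counts per direction."""
    ev = _in_window(log, window)
    out: dict[str, float] = {}
    for kind in CALL_TYPES:
        sub = ev[ev["type"] == kind]
        out[f"{kind}_count"] = float(len(sub))
        if kind in CALL_DURATION_TYPES:
            out[f"{kind}_duration_s"] = float(sub["duration_s"].sum())
    out["message_incoming_count"] = float((ev["type"] == "message_incoming").sum())
    out["message_outgoing_count"] = float((ev["type"] == "message_outgoing").sum())
    return out


def notification_features(log: pd.DataFrame, window: tuple[float, float],
                          app_map: dict[str, str] | None = None) -> dict[str, float]:
    """Notification counts per app category; unmapped packages count as Unknown."""
    app_map = load_app_category_map() if app_map is None else app_map
    ev = _in_window(log, window)
    ev = ev[ev["type"] == "notification"]
    cats = ev["app_package"].map(lambda p: app_map.get(p, "Unknown"))
    counts = cats.value_counts()
    return {f"notif_{c}": float(counts.get(c, 0)) for c in CATEGORIES}


def screen_sessions(log: pd.DataFrame) -> np.ndarray:
    """Sanitised screen-on intervals ``(start, end)`` from unlock/lock events.

    Duplicate/nested unlocks are merged (first unlock opens, first following
    lock closes); a trailing unlock without a lock stays open until +inf and
    is truncated at query time.
    """
    ev = log[log["type"].isin(["screen_unlock", "screen_lock"])].sort_values("t", kind="stable")
    intervals = []
    open_t = None
    for t, kind in zip(ev["t"].to_numpy(), ev["type"].to_numpy()):
        if kind == "screen_unlock":
            if open_t is None:
                open_t = t
        else:
            if open_t is not None and t > open_t:
                intervals.append((open_t, t))
                open_t = None
    if open_t is not None:
        intervals.append((open_t, np.inf))
    return np.array(intervals, dtype=float).reshape(-1, 2)


def screen_features(log: pd.DataFrame, window: tuple[float, float],
                    sessions: np.ndarray | None = None) -> dict[str, float]:
    """Unlock count and total screen-on time inside the window.

    Sessions crossing the window edge are clipped at the edge; an unlock with
    no matching lock is closed at the window end.
    """
    a, b = window
    if sessions is None:
        sessions = screen_sessions(log)
    unlocks = float(((log["type"] == "screen_unlock") & (log["t"] >= a) & (log["t"] < b)).sum())
    if len(sessions) == 0:
        return {"screen_unlock_count": unlocks, "screen_on_duration_s": 0.0}
    s = np.clip(sessions[:, 0], a, b)
    e = np.clip(sessions[:, 1], a, b)
    return {"screen_unlock_count": unlocks,
            "screen_on_duration_s": float(np.maximum(e - s, 0.0).sum())}
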