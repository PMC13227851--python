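"""Activity-bout extraction from thigh-worn accelerometer event streams.

An event stream is a sequence of contiguous posture/MET records (the atom
exported by event-based devices such as the activPAL).  Events are classified
by MET cut-points — sedentary (< 1.25 METs while seated or reclined), light
activity (1.25–2.99 METs), moderate-to-vigorous (≥ 3 METs) — and maximal
contiguous same-class runs become bouts.  Runs shorter than the 1-minute
recordable floor are relabelled OTHER and never feed the distribution
indices, as are sub-threshold standing periods.
"""

from __future__ import annotations

import datetime as _dt
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "BOUT_CLASSES",
    "POSTURES",
    "classify_event",
    "extract_bouts",
    "wear_time",
    "summarize_day",
    "dow_of",
    "read_events",
    "write_events",
    "adapt_activpal_events",
    "bouts_to_events",
]

BOUT_CLASSES = ("SED", "LPA", "MVPA")
POSTURES = ("seated_reclined", "standing", "stepping")

SED_MET_MAX = 1.25
MVPA_MET_MIN = 3.0

#: events separated by more than this are not contiguous (absorbs rounding
#: in exported event files, which are nominally gapless)
GAP_TOLERANCE_S = 1.0

EVENT_COLUMNS = ["subject_id", "start", "duration_s", "posture", "met"]


def dow_of(date) -> int:
    """Day of week coded 1=Sunday, 2–6=Monday..Friday, 7=Saturday."""
    d = pd.Timestamp(date)
    return (d.weekday() + 1) % 7 + 1


def classify_event(met: float, posture: str) -> str:
    """Classify one event by MET value and posture.

    SED requires both a sub-1.25 MET value and a seated/reclined posture;
    quiet standing below 1.25 METs is OTHER (neither sedentary nor active).
    """
    if not np.isfinite(met) or met < 0:
        raise ValueError(f"met must be finite and >= 0, got {met}")
    if posture not in POSTURES:
        raise ValueError(f"unknown posture {posture!r}")
    if met >= MVPA_MET_MIN:
        return "MVPA"
    if met >= SED_MET_MAX:
        return "LPA"
    if posture == "seated_reclined":
        return "SED"
    return "OTHER"


def _check_sorted_nonoverlapping(starts: np.ndarray, ends: np.ndarray) -> None:
    # 5 ms tolerance absorbs timestamp-serialisation rounding
    bad = np.nonzero(starts[1:] < ends[:-1] - 5e-3)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"overlapping events: event {i} ending {ends[i]:.3f}s overlaps "
            f"event {i + 1} starting {starts[i + 1]:.3f}s (epoch seconds)"
        )


def extract_bouts(events: pd.DataFrame, min_bout_min: float = 1.0) -> pd.DataFrame:
    """Merge contiguous same-class events into bouts for one subject.

    Events must be sorted by start and non-overlapping.  Maximal contiguous
    (gap ≤ 1 s) same-class runs form candidate bouts; SED/LPA/MVPA candidates
    shorter than ``min_bout_min`` are relabelled OTHER.  A bout's length is
    the sum of its member event durations and it is assigned to the calendar
    date of its start (bouts spanning midnight are not split).

    Returns a table ``subject_id, date, dow, cls, start, length_min``.
    """
    cols = ["subject_id", "date", "dow", "cls", "start", "length_min"]
    if len(events) == 0:
        return pd.DataFrame(columns=cols)
    ev = events.sort_values("start", kind="mergesort").reset_index(drop=True)
    if ev["subject_id"].nunique() > 1:
        raise ValueError("extract_bouts expects events from a single subject")
    start = pd.to_datetime(ev["start"])
    dur = ev["duration_s"].to_numpy(dtype=float)
    if np.any(dur <= 0):
        raise ValueError("event durations must be positive")
    t0 = start.astype("int64").to_numpy() / 1e9
    t1 = t0 + dur
    _check_sorted_nonoverlapping(t0, t1)

    cls = np.array([classify_event(m, p) for m, p in zip(ev["met"], ev["posture"])])
    # run breaks: class change or a gap above tolerance
    gap = t0[1:] - t1[:-1]
    new_run = np.concatenate([[True], (cls[1:] != cls[:-1]) | (gap > GAP_TOLERANCE_S)])
    run_id = np.cumsum(new_run) - 1

    sid = ev["subject_id"].iloc[0]
    rows = []
    for rid in range(run_id[-1] + 1):
        mask = run_id == rid
        length_min = dur[mask].sum() / 60.0
        c = cls[mask][0]
        if c in BOUT_CLASSES and length_min < min_bout_min:
            c = "OTHER"
        s = start[np.nonzero(mask)[0][0]]
        rows.append(
            {
                "subject_id": sid,
                "date": s.date(),
                "dow": dow_of(s),
                "cls": c,
                "start": s,
                "length_min": length_min,
            }
        )
    return pd.DataFrame(rows, columns=cols)


def wear_time(events: pd.DataFrame, date, wake_window: tuple[float, float] = (6.0, 22.0)) -> float:
    """Hours of event-covered time within the wake window on ``date``.

    ``wake_window`` is (start_hour, end_hour) in local clock time.  Event
    intervals are unioned before intersecting with the window, so overlapping
    or duplicated records never double-count.
    """
    lo_h, hi_h = wake_window
    if not 0 <= lo_h < hi_h <= 24:
        raise ValueError(f"malformed wake window {wake_window}")
    if len(events) == 0:
        return 0.0
    day = pd.Timestamp(date)
    w0 = (day + pd.Timedelta(hours=lo_h)).value / 1e9
    w1 = (day + pd.Timedelta(hours=hi_h)).value / 1e9
    t0 = pd.to_datetime(events["start"]).astype("int64").to_numpy() / 1e9
    t1 = t0 + events["duration_s"].to_numpy(dtype=float)
    a = np.clip(t0, w0, w1)
    b = np.clip(t1, w0, w1)
    keep = b > a
    if not keep.any():
        return 0.0
    a, b = a[keep], b[keep]
    order = np.argsort(a, kind="mergesort")
    a, b = a[order], b[order]
    total, cur_a, cur_b = 0.0, a[0], b[0]
    for s, e in zip(a[1:], b[1:]):
        if s > cur_b:
            total += cur_b - cur_a
            cur_a, cur_b = s, e
        else:
            cur_b = max(cur_b, e)
    total += cur_b - cur_a
    return total / 3600.0


def summarize_day(
    bouts: pd.DataFrame,
    events: pd.DataFrame,
    date,
    wake_window: tuple[float, float] = (6.0, 22.0),
) -> dict:
    """Per-class bout counts and wear hours for one subject-day."""
    day = pd.Timestamp(date).date()
    db = bouts[pd.to_datetime(bouts["date"]).dt.date == day] if len(bouts) else bouts
    counts = {c: int((db["cls"] == c).sum()) if len(db) else 0 for c in BOUT_CLASSES}
    sid = None
    for tab in (bouts, events):
        if len(tab):
            sid = tab["subject_id"].iloc[0]
            break
    return {
        "subject_id": sid,
        "date": day,
        "dow": dow_of(day),
        "wear_hours": wear_time(events, day, wake_window),
        "n_sed": counts["SED"],
        "n_lpa": counts["LPA"],
        "n_mvpa": counts["MVPA"],
    }


# ---------------------------------------------------------------------------
# I/O


def read_events(path) -> pd.DataFrame:
    """Read the event CSV dialect (subject_id, start, duration_s, posture, met)."""
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event file {path} missing columns: {sorted(missing)}")
    df["start"] = pd.to_datetime(df["start"])
    bad = df.index[(df["duration_s"] <= 0) | (df["met"] < 0) | ~df["posture"].isin(POSTURES)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ValueError(f"invalid event rows at lines {lines} of {path}")
    return df[EVENT_COLUMNS]


def write_events(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["start"] = pd.to_datetime(out["start"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    out[EVENT_COLUMNS].to_csv(path, index=False, float_format="%.10g")


_ACTIVPAL_CODE_TO_POSTURE = {0: "seated_reclined", 1: "standing", 2: "stepping"}


def adapt_activpal_events(df: pd.DataFrame, subject_id: str) -> pd.DataFrame:
    """Map an activPAL-events-style export onto the event dialect.

    Expects columns ``time`` (start), ``interval_s`` (duration),
    ``activity`` (0 sedentary / 1 standing / 2 stepping) and ``met``.
    """
    out = pd.DataFrame(
        {
            "subject_id": subject_id,
            "start": pd.to_datetime(df["time"]),
            "duration_s": df["interval_s"].astype(float),
            "posture": df["activity"].map(_ACTIVPAL_CODE_TO_POSTURE),
            "met": df["met"].astype(float),
        }
    )
    if out["posture"].isna().any():
        raise ValueError("unknown activPAL activity code (expected 0/1/2)")
    return out


_REPRESENTATIVE = {
    "SED": (1.0, "seated_reclined"),
    "LPA": (2.0, "standing"),
    "MVPA": (3.5, "stepping"),
    "OTHER": (1.0, "standing"),
}


def bouts_to_events(bouts: pd.DataFrame) -> pd.DataFrame:
    """Project bouts back to a one-event-per-bout stream (for round-trips)."""
    rows = []
    for _, b in bouts.iterrows():
        met, posture = _REPRESENTATIVE[b["cls"]]
        rows.append(
            {
                "subject_id": b["subject_id"],
                "start": pd.Timestamp(b["start"]),
                "duration_s": float(b["length_min"]) * 60.0,
                "posture": posture,
                "met": met,
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
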