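"""Event classification, bout merging, the 1-minute floor, and wear time."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import boutcog as bc
from boutcog.bouts import bouts_to_events, read_events, write_events

from conftest import toy_events


@pytest.mark.parametrize(
    "met, posture, expected",
    [
        (1.0, "seated_reclined", "SED"),
        (1.24, "seated_reclined", "SED"),
        (1.25, "seated_reclined", "LPA"),  # boundary: 1.25 is LPA regardless of posture
        (1.25, "standing", "LPA"),
        (2.99, "stepping", "LPA"),
        (3.0, "stepping", "MVPA"),
        (6.0, "stepping", "MVPA"),
        (1.0, "standing", "OTHER"),  # quiet standing below 1.25 METs
        (0.0, "stepping", "OTHER"),
    ],
)
def test_classify_event_boundaries(met, posture, expected):
    assert bc.classify_event(met, posture) == expected


def test_classify_event_rejects_negative_met():
    with pytest.raises(ValueError):
        bc.classify_event(-0.1, "standing")


def test_sub_minute_run_is_not_a_bout():
    ev = toy_events([(0, 50 / 60, 3.5, "stepping")])  # 50 s of MVPA-intensity stepping
    bouts = bc.extract_bouts(ev)
    assert (bouts["cls"] == "MVPA").sum() == 0
    assert bouts.iloc[0]["cls"] == "OTHER"


def test_single_long_seated_event_is_one_bout():
    ev = toy_events([(0, 30.0, 1.0, "seated_reclined")])
    bouts = bc.extract_bouts(ev)
    assert len(bouts) == 1
    b = bouts.iloc[0]
    assert b["cls"] == "SED" and b["length_min"] == pytest.approx(30.0)
    assert b["dow"] == 2  # 2024-03-04 is a Monday


def test_contiguous_same_class_events_merge():
    ev = toy_events(
        [(0, 10.0, 1.0, "seated_reclined"), (10, 5.0, 1.1, "seated_reclined")]
    )
    bouts = bc.extract_bouts(ev)
    assert len(bouts) == 1
    assert bouts.iloc[0]["length_min"] == pytest.approx(15.0)


def test_gap_breaks_bout_and_class_change_breaks_bout():
    ev = toy_events(
        [
            (0, 5.0, 1.0, "seated_reclined"),
            (5.5, 5.0, 1.0, "seated_reclined"),  # 30 s gap: separate bouts
            (10.5, 5.0, 2.0, "stepping"),  # class change: LPA
        ]
    )
    bouts = bc.extract_bouts(ev)
    assert list(bouts["cls"]) == ["SED", "SED", "LPA"]


def test_overlapping_events_rejected_with_pair():
    ev = toy_events([(0, 10.0, 1.0, "seated_reclined"), (5, 10.0, 1.0, "seated_reclined")])
    with pytest.raises(ValueError, match="overlap"):
        bc.extract_bouts(ev)


def test_extract_bouts_idempotent_on_projection():
    rng = np.random.default_rng(3)
    segs, t = [], 0.0
    for _ in range(40):
        cls = rng.choice(["sed", "lpa", "mvpa", "other"])
        dur = float(rng.uniform(1.2, 20.0))
        met, posture = {
            "sed": (1.0, "seated_reclined"),
            "lpa": (2.0, "standing"),
            "mvpa": (3.5, "stepping"),
            "other": (1.0, "standing"),
        }[cls]
        segs.append((t, dur, met, posture))
        t += dur + (0.5 if rng.random() < 0.3 else 0.0)  # occasional gaps
    first = bc.extract_bouts(toy_events(segs))
    second = bc.extract_bouts(bouts_to_events(first))
    a = first[first.cls != "OTHER"].reset_index(drop=True)
    b = second[second.cls != "OTHER"].reset_index(drop=True)
    assert list(a["cls"]) == list(b["cls"])
    assert np.allclose(a["length_min"], b["length_min"])


def test_wear_time_conservation_and_gaps():
    # events tiling a 16-h wake window
    full = toy_events([(360 + 60 * k, 60.0, 1.0, "standing") for k in range(16)])
    assert bc.wear_time(full, "2024-03-04", (6.0, 22.0)) == pytest.approx(16.0)
    assert bc.wear_time(full.iloc[:0], "2024-03-04", (6.0, 22.0)) == 0.0
    # 12 h covered with a 2-h hole inside the window
    gap = toy_events(
        [(360 + 60 * k, 60.0, 1.0, "standing") for k in list(range(6)) + list(range(8, 14))]
    )
    assert bc.wear_time(gap, "2024-03-04", (6.0, 22.0)) == pytest.approx(12.0)


@settings(derandomize=True, max_examples=40)
@given(st.lists(st.floats(min_value=0.2, max_value=90.0), min_size=1, max_size=30))
def test_bout_plus_other_durations_conserve_wear_time(durations):
    """Total segment time (bouts + OTHER) equals event-covered wear time."""
    segs, t = [], 0.0
    rng = np.random.default_rng(0)
    for dur in durations:
        met, posture = [(1.0, "seated_reclined"), (2.0, "standing"), (3.5, "stepping"), (1.0, "standing")][
            rng.integers(4)
        ]
        segs.append((t, dur, met, posture))
        t += dur
    if t > 16 * 60:  # keep inside the wake window
        return
    ev = toy_events([(360 + m, d, met, p) for (m, d, met, p) in segs])
    bouts = bc.extract_bouts(ev)
    total_bout_min = bouts["length_min"].sum()
    wear_h = bc.wear_time(ev, "2024-03-04", (6.0, 22.0))
    assert total_bout_min == pytest.approx(wear_h * 60.0, abs=1.0 / 60.0)


def test_no_short_class_bout_in_any_output():
    rng = np.random.default_rng(9)
    segs, t = [], 0.0
    for _ in range(60):
        dur = float(rng.uniform(0.2, 5.0))
        met, posture = [(1.0, "seated_reclined"), (2.0, "standing"), (3.5, "stepping")][rng.integers(3)]
        segs.append((t, dur, met, posture))
        t += dur
    bouts = bc.extract_bouts(toy_events(segs))
    cls_bouts = bouts[bouts["cls"].isin(("SED", "LPA", "MVPA"))]
    assert (cls_bouts["length_min"] >= 1.0).all()


def test_summarize_day_counts_match_brute_force():
    rng = np.random.default_rng(4)
    segs, t = [], 0.0
    for _ in range(30):
        dur = float(rng.uniform(1.5, 10.0))
        met, posture = [(1.0, "seated_reclined"), (2.0, "standing"), (3.5, "stepping")][rng.integers(3)]
        segs.append((t, dur, met, posture))
        t += dur
    ev = toy_events(segs)
    bouts = bc.extract_bouts(ev)
    summary = bc.summarize_day(bouts, ev, "2024-03-04")
    for cls, key in (("SED", "n_sed"), ("LPA", "n_lpa"), ("MVPA", "n_mvpa")):
        assert summary[key] == int((bouts["cls"] == cls).sum())
    # permutation invariance of the count
    shuffled = bouts.sample(frac=1.0, random_state=1)
    assert bc.summarize_day(shuffled, ev, "2024-03-04")["n_sed"] == summary["n_sed"]


def test_event_csv_roundtrip_and_validation(tmp_path):
    ev = toy_events([(0, 5.0, 1.0, "seated_reclined"), (5, 2.0, 3.2, "stepping")])
    path = tmp_path / "events.csv"
    write_events(ev, path)
    back = read_events(path)
    assert np.allclose(back["duration_s"], ev["duration_s"])
    assert list(back["posture"]) == list(ev["posture"])
    bad = ev.copy()
    bad.loc[1, "met"] = -1.0
    write_events(bad, path)
    with pytest.raises(ValueError, match="lines"):
        read_events(path)


def test_dow_coding_sunday_is_one():
    assert bc.dow_of("2024-03-03") == 1  # Sunday
    assert bc.dow_of("2024-03-04") == 2  # Monday
    assert bc.dow_of("2024-03-09") == 7  # Saturday
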