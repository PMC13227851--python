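"""Alpha and Gini index estimators and their day-of-week aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import boutcog as bc
from boutcog.indices import BoutLengthSample

from conftest import gini_double_loop

lengths_strategy = st.lists(
    st.floats(min_value=1.0, max_value=500.0, allow_nan=False), min_size=1, max_size=60
)


@pytest.mark.parametrize(
    "lengths, expected",
    [
        ([5, 5, 5, 5], 0.0),
        ([1, 4], 0.3),
        ([1, 1, 8], 7.0 / 15.0),
        ([3.0], 0.0),
    ],
)
def test_gini_hand_cases(lengths, expected):
    assert bc.gini_index(lengths) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "lengths, expected",
    [
        ([np.e], 2.0),
        ([1.0, np.e**2, 1.0], 2.5),
    ],
)
def test_alpha_hand_cases(lengths, expected):
    assert bc.alpha_index(lengths, x_min=1.0) == pytest.approx(expected, abs=1e-12)


def test_alpha_degenerate_and_empty():
    assert np.isnan(bc.alpha_index([1.0, 1.0, 1.0], x_min=1.0))  # all at the floor
    assert np.isnan(bc.alpha_index([], x_min=1.0))
    assert np.isnan(bc.gini_index([]))


def test_index_input_errors():
    with pytest.raises(ValueError):
        bc.gini_index([1.0, -2.0])
    with pytest.raises(ValueError):
        bc.alpha_index([0.5], x_min=1.0)  # below the recordable floor
    with pytest.raises(ValueError):
        BoutLengthSample((1.0,), x_min=0.0)


@settings(derandomize=True, max_examples=150)
@given(lengths_strategy)
def test_gini_matches_double_loop_oracle(lengths):
    assert bc.gini_index(lengths) == pytest.approx(gini_double_loop(lengths), abs=1e-10)


@settings(derandomize=True, max_examples=100)
@given(lengths_strategy, st.floats(min_value=1e-3, max_value=1e3))
def test_gini_scale_invariance_and_bound(lengths, c):
    x = np.asarray(lengths)
    g = bc.gini_index(x)
    assert bc.gini_index(c * x) == pytest.approx(g, abs=1e-12)
    assert 0.0 <= g <= 1.0 - 1.0 / len(x) + 1e-12


@settings(derandomize=True, max_examples=100)
@given(lengths_strategy, st.floats(min_value=0.1, max_value=10.0))
def test_alpha_joint_scale_invariance(lengths, c):
    a = bc.alpha_index(lengths, x_min=1.0)
    a2 = bc.alpha_index([c * v for v in lengths], x_min=c)
    if np.isnan(a):
        assert np.isnan(a2)
    else:
        assert a2 == pytest.approx(a, rel=1e-10)


def test_alpha_estimator_consistency_on_pareto():
    """The estimator is the Pareto MLE, so it should recover the shape."""
    rng = np.random.default_rng(123)
    for shape in (2.0, 2.5, 3.5):
        x = bc.sample_bout_lengths(shape, 10_000, rng)
        assert bc.alpha_index(x, x_min=1.0) == pytest.approx(shape, abs=0.05)


def _bout_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "date", "dow", "cls", "length_min"])


def _valid_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "date", "dow"])


def test_dow_indices_pools_valid_same_dow_days():
    # two valid Mondays with identical bout multisets: pooled == single-day
    bouts = _bout_frame(
        [("A", "2024-03-04", 2, "SED", ln) for ln in (2.0, 5.0, 11.0)]
        + [("A", "2024-03-11", 2, "SED", ln) for ln in (2.0, 5.0, 11.0)]
    )
    valid = _valid_frame([("A", "2024-03-04", 2), ("A", "2024-03-11", 2)])
    out = bc.dow_indices(bouts, valid)
    sed = out[(out.cls == "SED") & (out.dow == 2)].iloc[0]
    assert sed["gini"] == pytest.approx(gini_double_loop([2.0, 5.0, 11.0]), abs=1e-12)
    assert sed["n_bouts_per_day"] == 3.0
    assert sed["n_days_contributing"] == 2


def test_dow_indices_skips_invalid_days_and_flags_empty_classes():
    bouts = _bout_frame(
        [("A", "2024-03-04", 2, "SED", 4.0), ("A", "2024-03-11", 2, "SED", 400.0)]
    )
    valid = _valid_frame([("A", "2024-03-04", 2)])  # second Monday invalid
    out = bc.dow_indices(bouts, valid)
    sed = out[(out.cls == "SED") & (out.dow == 2)].iloc[0]
    assert sed["gini"] == 0.0  # only the single valid-day bout contributes
    mvpa = out[(out.cls == "MVPA") & (out.dow == 2)].iloc[0]
    assert np.isnan(mvpa["alpha"]) and np.isnan(mvpa["gini"])
    assert mvpa["n_bouts_per_day"] == 0.0


def test_dow_aggregation_modes_differ_only_in_index_definition():
    bouts = _bout_frame(
        [("A", "2024-03-04", 2, "LPA", ln) for ln in (1.0, 9.0)]
        + [("A", "2024-03-11", 2, "LPA", ln) for ln in (4.0, 6.0)]
    )
    valid = _valid_frame([("A", "2024-03-04", 2), ("A", "2024-03-11", 2)])
    pooled = bc.dow_indices(bouts, valid, aggregation="pool")
    per_day = bc.dow_indices(bouts, valid, aggregation="per_day_mean")
    lp = pooled[pooled.cls == "LPA"].iloc[0]
    ld = per_day[per_day.cls == "LPA"].iloc[0]
    assert lp["gini"] == pytest.approx(gini_double_loop([1, 9, 4, 6]), abs=1e-12)
    assert ld["gini"] == pytest.approx(
        np.mean([gini_double_loop([1, 9]), gini_double_loop([4, 6])]), abs=1e-12
    )
    # counts identical across modes
    assert lp["n_bouts_per_day"] == ld["n_bouts_per_day"] == 2.0


def test_index_report_rows_and_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    rows, valid_rows = [], []
    for s in ("A", "B"):
        for date, dow in (("2024-03-03", 1), ("2024-03-04", 2)):
            valid_rows.append((s, date, dow))
            for cls in ("SED", "LPA"):
                for _ in range(3):
                    rows.append((s, date, dow, cls, 1.0 + float(rng.random() * 9)))
    out = bc.index_report(bc.dow_indices(_bout_frame(rows), _valid_frame(valid_rows)))
    # brute-force row count: subjects x dows x 3 classes
    assert len(out) == 2 * 2 * 3
    path = tmp_path / "idx.csv"
    out.to_csv(path, index=False)
    back = pd.read_csv(path)
    assert back["alpha"].isna().equals(out["alpha"].isna())
    assert np.allclose(back["gini"].fillna(-1), out["gini"].fillna(-1))
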