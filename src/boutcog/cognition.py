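"""Symbol-search EMA aggregation: trials -> sessions -> day-level outcomes.

Each prompt delivers an 18-trial speeded two-alternative forced-choice task.
The two primary outcomes are the median response time (RT) of accurate trials
and the number of correct trials, aggregated to the day level.  Only complete
sessions (all 18 trials answered) count toward a day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bouts import dow_of

__all__ = [
    "TRIALS_PER_SESSION",
    "summarize_session",
    "summarize_sessions",
    "aggregate_day",
    "aggregate_days",
    "read_trials",
    "write_trials",
]

TRIALS_PER_SESSION = 18

TRIAL_COLUMNS = ["subject_id", "session_start", "trial_index", "rt_ms", "correct"]


def summarize_session(trials: pd.DataFrame, trials_per_session: int = TRIALS_PER_SESSION) -> dict:
    """Summarise one session's trials.

    ``median_rt_accurate`` is the midpoint-convention median over accurate
    trials, NaN if no trial was accurate; ``complete`` requires exactly
    ``trials_per_session`` trials.
    """
    if trials["trial_index"].duplicated().any():
        dup = trials.loc[trials["trial_index"].duplicated(), "trial_index"].iloc[0]
        raise ValueError(f"duplicate trial_index {dup} within a session")
    correct = trials["correct"].astype(bool)
    acc_rt = trials.loc[correct, "rt_ms"].to_numpy(dtype=float)
    return {
        "subject_id": trials["subject_id"].iloc[0],
        "session_start": pd.Timestamp(trials["session_start"].iloc[0]),
        "date": pd.Timestamp(trials["session_start"].iloc[0]).date(),
        "n_trials": int(len(trials)),
        "n_correct": int(correct.sum()),
        "median_rt_accurate": float(np.median(acc_rt)) if acc_rt.size else float("nan"),
        "complete": len(trials) == trials_per_session,
    }


def summarize_sessions(trials: pd.DataFrame, trials_per_session: int = TRIALS_PER_SESSION) -> pd.DataFrame:
    """Session summaries for a whole trial table (grouped by subject, session)."""
    rows = [
        summarize_session(g, trials_per_session)
        for _, g in trials.groupby(["subject_id", "session_start"], sort=True)
    ]
    cols = ["subject_id", "session_start", "date", "n_trials", "n_correct", "median_rt_accurate", "complete"]
    return pd.DataFrame(rows, columns=cols)


def aggregate_day(
    trials: pd.DataFrame,
    trials_per_session: int = TRIALS_PER_SESSION,
    rt_mode: str = "pooled",
) -> dict:
    """Day-level outcomes from one subject-date's trials.

    Only complete sessions contribute.  With ``rt_mode="pooled"`` (default)
    the day RT is the median of all accurate-trial RTs pooled across the
    day's complete sessions; ``"session_median_mean"`` instead averages the
    per-session medians.  ``mean_correct`` is the mean of per-session correct
    counts.  Sessions with zero accurate trials still count as complete but
    contribute no RTs.
    """
    if rt_mode not in ("pooled", "session_median_mean"):
        raise ValueError(f"unknown rt_mode {rt_mode!r}")
    sessions = summarize_sessions(trials, trials_per_session)
    complete = sessions[sessions["complete"]]
    date = pd.Timestamp(trials["session_start"].iloc[0]).date()
    out = {
        "subject_id": trials["subject_id"].iloc[0],
        "date": date,
        "dow": dow_of(date),
        "n_complete_sessions": int(len(complete)),
        "median_rt": float("nan"),
        "mean_correct": float("nan"),
    }
    if len(complete) == 0:
        return out
    out["mean_correct"] = float(complete["n_correct"].mean())
    complete_starts = set(complete["session_start"])
    mask = trials["session_start"].map(lambda s: pd.Timestamp(s) in complete_starts)
    pooled = trials[mask & trials["correct"].astype(bool)]["rt_ms"].to_numpy(dtype=float)
    if rt_mode == "pooled":
        if pooled.size:
            out["median_rt"] = float(np.median(pooled))
    else:
        med = complete["median_rt_accurate"].dropna()
        if len(med):
            out["median_rt"] = float(med.mean())
    return out


def aggregate_days(
    trials: pd.DataFrame,
    trials_per_session: int = TRIALS_PER_SESSION,
    rt_mode: str = "pooled",
) -> pd.DataFrame:
    """Day-level cognitive outcomes for a whole trial table."""
    t = trials.copy()
    t["_date"] = pd.to_datetime(t["session_start"]).dt.date
    rows = [
        aggregate_day(g.drop(columns="_date"), trials_per_session, rt_mode)
        for _, g in t.groupby(["subject_id", "_date"], sort=True)
    ]
    cols = ["subject_id", "date", "dow", "n_complete_sessions", "median_rt", "mean_correct"]
    return pd.DataFrame(rows, columns=cols)


def read_trials(path) -> pd.DataFrame:
    """Read the trial CSV dialect, rejecting malformed rows with line numbers."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial file {path} missing columns: {sorted(missing)}")
    if len(df) == 0:
        df["session_start"] = pd.to_datetime(df["session_start"])
        return df[TRIAL_COLUMNS]
    df["session_start"] = pd.to_datetime(df["session_start"])
    bad = df.index[(df["rt_ms"] <= 0) | ~df["correct"].isin([0, 1]) | (df["trial_index"] < 1)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]
        raise ValueError(f"invalid trial rows at lines {lines} of {path}")
    df["correct"] = df["correct"].astype(int)
    return df[TRIAL_COLUMNS]


def write_trials(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["session_start"] = pd.to_datetime(out["session_start"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out[TRIAL_COLUMNS].to_csv(path, index=False, float_format="%.10g")
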