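"""Valid-day rules and assembly of the day-of-week-matched analysis table.

A protocol day is valid when it has at least 10 h of accelerometer wear
during waking time and at least one fully completed cognitive session.
Valid days are then collapsed to one observation per (subject, day-of-week):
outcomes averaged over the (typically two) valid same-dow dates, joined with
the day-of-week bout-distribution indices and demographics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bouts import BOUT_CLASSES

__all__ = [
    "WEAR_HOURS_MIN",
    "SESSIONS_MIN",
    "EDUCATION_LEVELS",
    "flag_valid_days",
    "build_analysis_table",
    "exclusion_report",
]

WEAR_HOURS_MIN = 10.0
SESSIONS_MIN = 1

#: reference level first; the two indicator contrasts use the rest
EDUCATION_LEVELS = ("up_to_high_school", "some_college_bachelors", "advanced_degree")

ANALYSIS_INDEX_COLS = [
    f"{m}_{c.lower()}" for c in BOUT_CLASSES for m in ("alpha", "gini", "n_bouts")
]


def flag_valid_days(
    day_summaries: pd.DataFrame,
    cognitive_days: pd.DataFrame,
    wear_hours_min: float = WEAR_HOURS_MIN,
    sessions_min: int = SESSIONS_MIN,
) -> pd.DataFrame:
    """One record per observed protocol day with validity and exclusion reason.

    A date present in the cognition table but absent from accelerometry is
    kept with wear 0 (and therefore excluded as low wear).  When both rules
    fail, low wear takes precedence as the recorded reason.
    """
    acc = day_summaries[["subject_id", "date", "dow", "wear_hours"]].copy()
    cog = cognitive_days[["subject_id", "date", "dow", "n_complete_sessions"]].copy()
    for t in (acc, cog):
        t["date"] = pd.to_datetime(t["date"]).dt.date
    merged = acc.merge(cog, on=["subject_id", "date"], how="outer", suffixes=("", "_cog"))
    merged["dow"] = merged["dow"].fillna(merged.get("dow_cog"))
    merged["wear_hours"] = merged["wear_hours"].fillna(0.0)
    merged["n_complete_sessions"] = merged["n_complete_sessions"].fillna(0).astype(int)

    low_wear = merged["wear_hours"] < wear_hours_min
    no_ema = merged["n_complete_sessions"] < sessions_min
    merged["valid"] = ~(low_wear | no_ema)
    merged["exclusion_reason"] = np.where(
        low_wear, "low_wear", np.where(no_ema, "no_ema", "none")
    )
    cols = ["subject_id", "date", "dow", "wear_hours", "n_complete_sessions", "valid", "exclusion_reason"]
    out = merged[cols].copy()
    out["dow"] = out["dow"].astype(int)
    return out.sort_values(["subject_id", "date"], kind="mergesort").reset_index(drop=True)


def _education_contrasts(edu: pd.Series) -> pd.DataFrame:
    unknown = set(edu) - set(EDUCATION_LEVELS)
    if unknown:
        raise ValueError(f"unknown education levels: {sorted(unknown)}")
    return pd.DataFrame(
        {
            "edu_some_college": (edu == EDUCATION_LEVELS[1]).astype(int),
            "edu_advanced": (edu == EDUCATION_LEVELS[2]).astype(int),
        }
    )


def build_analysis_table(
    valid_days: pd.DataFrame,
    cognitive_days: pd.DataFrame,
    index_sets: pd.DataFrame,
    demographics: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble one row per (subject, dow) with outcomes, indices, covariates.

    Outcomes are means over the subject's valid dates on that dow (a day
    whose complete sessions had no accurate trial contributes to accuracy
    but not to RT).  Rows where all three classes' index sets are missing
    are dropped.  Subjects present in outcomes but absent from demographics
    raise.
    """
    vd = valid_days[valid_days["valid"]][["subject_id", "date", "dow"]].copy()
    vd["date"] = pd.to_datetime(vd["date"]).dt.date
    cog = cognitive_days.copy()
    cog["date"] = pd.to_datetime(cog["date"]).dt.date
    cog = vd.merge(cog.drop(columns=["dow"]), on=["subject_id", "date"], how="inner")

    y = (
        cog.groupby(["subject_id", "dow"], sort=True)
        .agg(median_rt=("median_rt", "mean"), mean_correct=("mean_correct", "mean"))
        .reset_index()
    )

    wide = index_sets.pivot_table(
        index=["subject_id", "dow"],
        columns="cls",
        values=["alpha", "gini", "n_bouts_per_day"],
        aggfunc="first",
    )
    wide.columns = [
        f"{'n_bouts' if m == 'n_bouts_per_day' else m}_{c.lower()}" for m, c in wide.columns
    ]
    wide = wide.reset_index()

    tab = y.merge(wide, on=["subject_id", "dow"], how="left")
    for col in ANALYSIS_INDEX_COLS:
        if col not in tab.columns:
            tab[col] = np.nan

    # drop rows with no index information in any class
    idx_cols = [c for c in ANALYSIS_INDEX_COLS if c.startswith(("alpha", "gini"))]
    tab = tab[~tab[idx_cols].isna().all(axis=1)].copy()

    demo = demographics[["subject_id", "age", "sex", "education"]].copy()
    missing = sorted(set(tab["subject_id"]) - set(demo["subject_id"]))
    if missing:
        raise ValueError(f"subjects missing from demographics: {missing}")
    demo = pd.concat([demo, _education_contrasts(demo["education"])], axis=1)
    tab = tab.merge(demo.drop(columns=["education"]), on="subject_id", how="left")

    cols = (
        ["subject_id", "dow", "median_rt", "mean_correct"]
        + ANALYSIS_INDEX_COLS
        + ["age", "sex", "edu_some_college", "edu_advanced"]
    )
    return tab[cols].sort_values(["subject_id", "dow"], kind="mergesort").reset_index(drop=True)


def exclusion_report(valid_day_records: pd.DataFrame, n_protocol_days: int | None = None) -> dict:
    """Counts and percentages of excluded person-days by reason.

    ``n_protocol_days`` sets the person-day denominator as
    subjects × protocol days; by default the observed record count is used.
    """
    n_subjects = int(valid_day_records["subject_id"].nunique())
    n_obs = int(len(valid_day_records))
    denom = n_subjects * n_protocol_days if n_protocol_days else n_obs
    n_valid = int(valid_day_records["valid"].sum())
    by_reason = (
        valid_day_records.loc[~valid_day_records["valid"], "exclusion_reason"]
        .value_counts()
        .to_dict()
    )
    n_excluded = denom - n_valid
    return {
        "n_subjects": n_subjects,
        "n_person_days": denom,
        "n_observed_days": n_obs,
        "n_valid": n_valid,
        "n_excluded": n_excluded,
        "pct_excluded": 100.0 * n_excluded / denom if denom else 0.0,
        "by_reason": {str(k): int(v) for k, v in by_reason.items()},
    }
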