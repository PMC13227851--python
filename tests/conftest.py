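"""Shared fixtures: small synthetic cohorts and toy event streams."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import boutcog as bc
from boutcog.simulate import _zero_curves


def null_config(**kw) -> bc.SimConfig:
    """SimConfig with all planted effects zeroed."""
    base = dict(planted_beta_gini=_zero_curves(), planted_beta_alpha=_zero_curves())
    base.update(kw)
    return bc.SimConfig(**base)


@pytest.fixture(scope="session")
def small_cohort() -> bc.SyntheticCohort:
    """Full-fidelity cohort: 6 subjects x 14 days, full compliance, no QC loss."""
    return bc.generate_cohort(
        bc.SimConfig(n_subjects=6, n_days=14, compliance=1.0, low_wear_prob=0.0, seed=42)
    )


@pytest.fixture(scope="session")
def messy_cohort() -> bc.SyntheticCohort:
    """Cohort with injected low-wear days and missed prompts."""
    return bc.generate_cohort(
        bc.SimConfig(n_subjects=10, n_days=14, compliance=0.6, low_wear_prob=0.15, seed=7)
    )


@pytest.fixture(scope="session")
def dow_table_300():
    """Day-level analysis table, 300 subjects, default planted effects."""
    tab, truth = bc.simulate_dow_table(bc.SimConfig(n_subjects=300), seed=5)
    return tab, truth


def toy_events(segments, subject_id="T01", day="2024-03-04"):
    """Build an event table from (start_minute, duration_min, met, posture) tuples."""
    day = pd.Timestamp(day)
    rows = [
        {
            "subject_id": subject_id,
            "start": day + pd.Timedelta(minutes=m),
            "duration_s": dur * 60.0,
            "posture": posture,
            "met": met,
        }
        for (m, dur, met, posture) in segments
    ]
    return pd.DataFrame(rows)


def gini_double_loop(x) -> float:
    """O(n^2) reference implementation straight from the defining formula."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        return float("nan")
    return float(np.sum(np.abs(x[:, None] - x[None, :])) / (2.0 * n * x.sum()))
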