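"""Bout-length distribution indices: alpha (power-law tail) and Gini (inequality).

Both indices summarise the multiset of bout lengths of one activity class
(sedentary, light, or moderate-to-vigorous) accumulated on one day of the
week.  The alpha index,

    alpha = 1 + 1 / M,      M = mean_i log(x_i / x_min),

is the maximum-likelihood tail exponent of a Pareto distribution with known
scale ``x_min`` (the shortest recordable bout, 1 minute for event-based
accelerometry).  Higher alpha means short bouts dominate; lower alpha means
activity is consolidated into long, sustained bouts.  The Gini index is half
the relative mean absolute pairwise difference,

    G = sum_ij |x_i - x_j| / (2 n sum_i x_i),

in [0, 1): 0 for perfectly even bout lengths, approaching 1 when a few very
long bouts coexist with many short ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bouts import BOUT_CLASSES

__all__ = [
    "BoutLengthSample",
    "gini_index",
    "alpha_index",
    "dow_indices",
    "index_report",
]


@dataclass(frozen=True)
class BoutLengthSample:
    """Bout lengths (minutes) of one class, with the recording floor ``x_min``.

    ``x_min`` is an instrument property (the minimum bout duration), not the
    sample minimum; it must be fixed from configuration.
    """

    lengths: tuple[float, ...]
    x_min: float = 1.0

    def __post_init__(self) -> None:
        if self.x_min <= 0:
            raise ValueError(f"x_min must be positive, got {self.x_min}")
        object.__setattr__(self, "lengths", tuple(float(x) for x in self.lengths))

    @property
    def n(self) -> int:
        return len(self.lengths)


def _as_lengths(sample) -> np.ndarray:
    if isinstance(sample, BoutLengthSample):
        return np.asarray(sample.lengths, dtype=float)
    return np.asarray(list(sample), dtype=float)


def gini_index(sample) -> float:
    """Sample Gini index of bout lengths; NaN for an empty sample.

    Computed in O(n log n) from the sorted sample,
    ``G = sum_i (2i - n - 1) x_(i) / (n sum x)`` which is algebraically
    identical to the half relative mean absolute difference.
    """
    x = _as_lengths(sample)
    if x.size == 0:
        return float("nan")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("bout lengths must be positive and finite")
    n = x.size
    total = x.sum()
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    g = float(((2 * i - n - 1) * xs).sum() / (n * total))
    # guard tiny negative round-off on near-equal samples
    return max(g, 0.0)


def alpha_index(sample, x_min: float | None = None) -> float:
    """Pareto tail exponent estimate ``1 + 1/mean(log(x/x_min))``.

    Returns NaN (degenerate) when the sample is empty or every bout sits at
    the recording floor (M = 0); downstream models treat NaN as missing.
    Lengths below ``x_min`` are a contract violation and raise.
    """
    if x_min is None:
        x_min = sample.x_min if isinstance(sample, BoutLengthSample) else 1.0
    x = _as_lengths(sample)
    if x.size == 0:
        return float("nan")
    if np.any(x < x_min * (1 - 1e-12)):
        raise ValueError(f"bout length below the recording floor x_min={x_min}")
    m = float(np.mean(np.log(np.maximum(x, x_min) / x_min)))
    if m == 0.0:
        return float("nan")
    return 1.0 + 1.0 / m


def dow_indices(
    bouts: pd.DataFrame,
    valid_dates: pd.DataFrame,
    x_min: float = 1.0,
    aggregation: str = "pool",
) -> pd.DataFrame:
    """Day-of-week indices per (subject, dow, class) from valid days only.

    Parameters
    ----------
    bouts
        Bout table (``subject_id, date, dow, cls, length_min``); OTHER
        segments are ignored.
    valid_dates
        Table with ``subject_id, date, dow`` listing the valid wear days
        that define each subject's day-of-week samples.
    aggregation
        ``"pool"`` (default): pool bout lengths across the subject's valid
        dates on that dow before computing each index.  ``"per_day_mean"``:
        compute per-date indices and average the non-missing ones.

    Returns one row per (subject, dow, class) for every dow with at least one
    valid date; ``alpha``/``gini`` are NaN when the class has no bouts there,
    ``n_bouts_per_day`` is the mean daily count over the dow's valid dates,
    and ``n_days_contributing`` counts those valid dates.
    """
    if aggregation not in ("pool", "per_day_mean"):
        raise ValueError(f"unknown aggregation mode {aggregation!r}")
    vd = valid_dates[["subject_id", "date", "dow"]].drop_duplicates()
    cb = bouts[bouts["cls"].isin(BOUT_CLASSES)]
    cb = cb.merge(vd[["subject_id", "date"]], on=["subject_id", "date"], how="inner")

    rows = []
    grouped = {k: g for k, g in cb.groupby(["subject_id", "dow", "cls"], sort=False)}
    for (sid, dow), days in vd.groupby(["subject_id", "dow"], sort=False):
        n_days = len(days)
        for cls in BOUT_CLASSES:
            g = grouped.get((sid, dow, cls))
            if g is None or len(g) == 0:
                alpha, gini, n_per_day = float("nan"), float("nan"), 0.0
            else:
                lengths = g["length_min"].to_numpy(dtype=float)
                if aggregation == "pool":
                    alpha = alpha_index(lengths, x_min=x_min)
                    gini = gini_index(lengths)
                else:
                    per_a, per_g = [], []
                    for _, dg in g.groupby("date", sort=False):
                        xs = dg["length_min"].to_numpy(dtype=float)
                        per_a.append(alpha_index(xs, x_min=x_min))
                        per_g.append(gini_index(xs))
                    alpha = float(np.nanmean(per_a)) if np.any(np.isfinite(per_a)) else float("nan")
                    gini = float(np.nanmean(per_g)) if np.any(np.isfinite(per_g)) else float("nan")
                n_per_day = len(g) / n_days
            rows.append(
                {
                    "subject_id": sid,
                    "dow": int(dow),
                    "cls": cls,
                    "alpha": alpha,
                    "gini": gini,
                    "n_bouts_per_day": n_per_day,
                    "n_days_contributing": n_days,
                }
            )
    cols = ["subject_id", "dow", "cls", "alpha", "gini", "n_bouts_per_day", "n_days_contributing"]
    return pd.DataFrame(rows, columns=cols)


def index_report(indexsets: pd.DataFrame) -> pd.DataFrame:
    """Tidy index table with a stable column order and explicit missingness."""
    cols = ["subject_id", "dow", "cls", "alpha", "gini", "n_bouts_per_day", "n_days_contributing"]
    out = indexsets[cols].sort_values(["subject_id", "dow", "cls"], kind="mergesort")
    return out.reset_index(drop=True)
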