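"""Synthetic EMA + accelerometer cohort generator.

Emulates a 14-day ambulatory protocol in older adults: an event-based
thigh accelerometer stream (sedentary / light / moderate-to-vigorous bouts
with a 1-minute floor and heavy-tailed Pareto lengths, tiled into a wake
window with OTHER filler), four semi-random cognitive prompts per day of 18
symbol-search trials each, and demographics.  Day-level cognitive outcome
means follow a linear model in the day's true bout-distribution indices with
planted day-of-week-varying coefficients, a subject random intercept (the
ICC knob) and a day residual; sessions add trial-level measurement noise on
top.  The planted curves and per-day true indices are returned as ground
truth so downstream recovery can be scored without re-derivation.

Two granularities are provided: :func:`generate_cohort` emits full event and
trial tables for end-to-end pipeline runs, while :func:`simulate_dow_table`
draws the same bout-length and outcome model directly at the day level
(vectorised, with an analytic approximation of the trial-sampling noise) for
Monte-Carlo calibration studies where thousands of cohorts are needed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bouts import BOUT_CLASSES, dow_of
from .qc import EDUCATION_LEVELS

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_day_events",
    "generate_session_trials",
    "true_indices",
    "sample_bout_lengths",
    "simulate_dow_table",
    "write_cohort",
]

OUTCOMES = ("median_rt", "mean_correct")

#: SE of a sample median relative to sigma/sqrt(n) for Gaussian-ish noise
_MEDIAN_SE_FACTOR = 1.2533


def _zero_curves() -> dict:
    return {o: {c: (0.0,) * 7 for c in BOUT_CLASSES} for o in OUTCOMES}


def _default_beta_gini() -> dict:
    # qualitative shape of the reported associations: null on Sunday,
    # constant on weekdays, half-sized Saturday (RT in ms per unit Gini,
    # accuracy in trials per unit Gini)
    return {
        "median_rt": {
            "SED": (0.0, 300.0, 300.0, 300.0, 300.0, 300.0, 150.0),
            "LPA": (0.0,) * 7,
            "MVPA": (0.0, -600.0, -600.0, -600.0, -600.0, -600.0, -300.0),
        },
        "mean_correct": {
            "SED": (0.0,) * 7,
            "LPA": (0.0, 1.5, 1.5, 1.5, 1.5, 1.5, 0.75),
            "MVPA": (0.0,) * 7,
        },
    }


@dataclass(frozen=True)
class SimConfig:
    """Study-design and data-generating parameters of the synthetic cohort.

    Defaults mirror the emulated protocol: 87 subjects x 14 days, 4 prompts
    of 18 trials, daily bout counts near the observed means (sedentary 28,
    LPA 35, MVPA 7), Pareto bout lengths with a 1-min recordable floor, and
    subject/residual SDs giving ICC = subject_sd^2/(subject_sd^2+residual_sd^2)
    = 0.5 on each latent day-level outcome.
    """

    n_subjects: int = 87
    n_days: int = 14
    prompts_per_day: int = 4
    trials_per_session: int = 18
    compliance: float = 0.85
    wake_start: float = 6.0
    wake_end: float = 22.0
    x_min: float = 1.0
    bout_count_means: dict = field(
        default_factory=lambda: {"SED": 28.0, "LPA": 35.0, "MVPA": 7.0}
    )
    bout_length_tail: dict = field(
        default_factory=lambda: {"SED": 2.5, "LPA": 3.0, "MVPA": 3.5}
    )
    planted_beta_gini: dict = field(default_factory=_default_beta_gini)
    planted_beta_alpha: dict = field(default_factory=_zero_curves)
    subject_sd: dict = field(default_factory=lambda: {"median_rt": 250.0, "mean_correct": 0.3})
    residual_sd: dict = field(default_factory=lambda: {"median_rt": 250.0, "mean_correct": 0.3})
    rt_baseline: float = 2300.0
    accuracy_baseline: float = 17.5
    rt_sigma: float = 0.25  # lognormal SD of trial RTs within a session
    low_wear_prob: float = 0.0
    start_date: str = "2024-03-03"  # a Sunday
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.compliance <= 1 or not 0 <= self.low_wear_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if any(a <= 1 for a in self.bout_length_tail.values()):
            raise ValueError("Pareto tail shapes must exceed 1")
        if any(v < 0 for v in self.subject_sd.values()) or any(
            v < 0 for v in self.residual_sd.values()
        ):
            raise ValueError("SDs must be >= 0")
        if not 0 <= self.wake_start < self.wake_end <= 24:
            raise ValueError("malformed wake window")
        if self.n_days % 7 != 0:
            warnings.warn(
                f"n_days={self.n_days} is not a multiple of 7; day-of-week "
                "coverage will be unbalanced",
                stacklevel=2,
            )

    def icc(self, outcome: str) -> float:
        s2 = self.subject_sd[outcome] ** 2
        r2 = self.residual_sd[outcome] ** 2
        return s2 / (s2 + r2) if s2 + r2 > 0 else 0.0


@dataclass
class SyntheticCohort:
    events: pd.DataFrame
    trials: pd.DataFrame
    demographics: pd.DataFrame
    truth: dict


def sample_bout_lengths(shape: float, n: int, rng: np.random.Generator, x_min: float = 1.0) -> np.ndarray:
    """Draw n Pareto bout lengths (minutes) with scale ``x_min``.

    ``shape`` is the density exponent alpha (f(x) ~ x^-alpha, the convention
    of the bout-distribution literature and of the alpha index, whose
    population analogue is exactly ``shape``); the survival-tail exponent is
    ``shape - 1``, so shapes at or below 2 have infinite mean and real days
    only see them truncated by the waking window.
    """
    if shape <= 1:
        raise ValueError("Pareto shape (density exponent) must exceed 1")
    return (rng.pareto(shape - 1.0, n) + 1.0) * x_min


def true_indices(bouts, x_min: float = 1.0) -> dict:
    """Per-class (alpha, gini, n_bouts) from a day's generated bout list.

    Deliberately an independent code path from :mod:`boutcog.indices`
    (blockwise mean-absolute-difference Gini, reciprocal-sum alpha) so that
    agreement between the two is a meaningful cross-check.
    ``bouts`` is an iterable of (cls, length_min) pairs.
    """
    out = {}
    by_cls: dict[str, list[float]] = {c: [] for c in BOUT_CLASSES}
    for cls, length in bouts:
        if cls in by_cls:
            by_cls[cls].append(float(length))
    for cls, lengths in by_cls.items():
        x = np.asarray(lengths, dtype=float)
        n = x.size
        if n == 0:
            out[cls] = (float("nan"), float("nan"), 0)
            continue
        logsum = float(np.sum(np.log(x / x_min)))
        alpha = 1.0 + n / logsum if logsum > 0 else float("nan")
        sum_abs = 0.0
        for i0 in range(0, n, 512):
            blk = x[i0 : i0 + 512]
            sum_abs += float(np.abs(blk[:, None] - x[None, :]).sum())
        gini = sum_abs / (2.0 * n * float(x.sum()))
        out[cls] = (alpha, gini, int(n))
    return out


def generate_day_events(
    subject_id: str,
    date,
    config: SimConfig,
    rng: np.random.Generator,
    low_wear: bool | None = None,
):
    """One simulated day: events tiling the wake window plus the truth bouts.

    Returns ``(events, bouts, low_wear)`` where ``events`` is a list of event
    dicts tiling the covered window without gaps or overlap, ``bouts`` the
    planted (cls, length_min) list, and ``low_wear`` whether the day was
    deliberately under-covered (< 10 h of events).
    """
    if low_wear is None:
        low_wear = bool(rng.random() < config.low_wear_prob)
    day = pd.Timestamp(date)
    window_h = config.wake_end - config.wake_start
    if low_wear:
        cover_h = float(rng.uniform(4.0, 9.5))
    else:
        cover_h = window_h
    window_min = cover_h * 60.0
    frac = cover_h / window_h

    bouts: list[tuple[str, float]] = []
    for cls in BOUT_CLASSES:
        n = rng.poisson(config.bout_count_means[cls] * frac)
        for ln in sample_bout_lengths(config.bout_length_tail[cls], n, rng, config.x_min):
            bouts.append((cls, float(ln)))
    order = rng.permutation(len(bouts))
    bouts = [bouts[i] for i in order]

    filler_floor = 10.0 / 60.0  # keep same-class bouts separated
    while bouts and sum(b[1] for b in bouts) + (len(bouts) + 1) * filler_floor > window_min:
        bouts.pop(int(rng.integers(len(bouts))))
    n_fill = len(bouts) + 1
    slack = window_min - sum(b[1] for b in bouts) - n_fill * filler_floor
    fillers = filler_floor + rng.dirichlet(np.ones(n_fill)) * slack

    met_ranges = {"SED": (0.95, 1.24), "LPA": (1.25, 2.99), "MVPA": (3.0, 6.0)}
    events: list[dict] = []
    cursor = config.wake_start * 60.0  # minutes since midnight

    def emit(cls: str, length_min: float) -> None:
        nonlocal cursor
        if cls == "OTHER":
            pieces = [length_min]
            met_lo, met_hi = 0.9, 1.24
            posture_pool = ["standing"]
        else:
            met_lo, met_hi = met_ranges[cls]
            if rng.random() < 0.3 and length_min > 2.0 / 60.0:
                cut = float(rng.uniform(0.3, 0.7))
                pieces = [length_min * cut, length_min * (1 - cut)]
            else:
                pieces = [length_min]
            posture_pool = {
                "SED": ["seated_reclined"],
                "LPA": ["standing", "stepping"],
                "MVPA": ["stepping"],
            }[cls]
        for piece in pieces:
            events.append(
                {
                    "subject_id": subject_id,
                    "start": day + pd.Timedelta(minutes=cursor),
                    "duration_s": piece * 60.0,
                    "posture": posture_pool[int(rng.integers(len(posture_pool)))],
                    "met": float(rng.uniform(met_lo, met_hi)),
                }
            )
            cursor += piece

    for filler, bout in zip(fillers, bouts + [None]):
        emit("OTHER", float(filler))
        if bout is not None:
            emit(bout[0], bout[1])
    return events, bouts, low_wear


def generate_session_trials(
    day_mean_rt: float,
    day_mean_correct: float,
    config: SimConfig,
    rng: np.random.Generator,
    subject_id: str = "s",
    session_start=None,
) -> list[dict]:
    """One prompt's trials: Bernoulli correctness, log-normal RTs.

    The log-normal location is chosen so the session's median accurate RT is
    centred on ``day_mean_rt``; with ``rt_sigma = 0`` every RT equals it.
    """
    if not (math.isfinite(day_mean_rt) and math.isfinite(day_mean_correct)):
        raise ValueError("day means must be finite")
    T = config.trials_per_session
    if not 0 <= day_mean_correct <= T:
        raise ValueError(f"day_mean_correct must lie in [0, {T}]")
    p = day_mean_correct / T
    correct = rng.random(T) < p
    rts = day_mean_rt * np.exp(rng.normal(0.0, config.rt_sigma, T))
    ts = pd.Timestamp(session_start) if session_start is not None else pd.Timestamp("2024-03-03 09:00")
    return [
        {
            "subject_id": subject_id,
            "session_start": ts,
            "trial_index": i + 1,
            "rt_ms": float(max(rts[i], 1.0)),
            "correct": int(correct[i]),
        }
        for i in range(T)
    ]


def _draw_demographics(rng: np.random.Generator, subject_id: str) -> dict:
    age = float(np.clip(rng.normal(68.5, 7.0), 60.0, 91.0))
    sex = int(rng.random() < 0.38)
    edu = EDUCATION_LEVELS[int(rng.choice(3, p=[0.195, 0.736, 0.069]))]
    return {"subject_id": subject_id, "age": age, "sex": sex, "education": edu}


def _planted_effect(config: SimConfig, outcome: str, dow: int, idx: dict) -> float:
    eff = 0.0
    for cls in BOUT_CLASSES:
        alpha, gini, _n = idx[cls]
        bg = config.planted_beta_gini[outcome][cls][dow - 1]
        ba = config.planted_beta_alpha[outcome][cls][dow - 1]
        if np.isfinite(gini):
            eff += bg * gini
        if np.isfinite(alpha):
            eff += ba * alpha
    return eff


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate the full cohort: events, trials, demographics, ground truth.

    One RNG stream per subject, split per day, so a fixed seed yields
    byte-identical tables regardless of generation order.
    """
    root = np.random.SeedSequence(config.seed)
    subject_seqs = root.spawn(config.n_subjects)
    start = pd.Timestamp(config.start_date)

    all_events, all_trials, demo_rows, truth_rows = [], [], [], []
    for si, seq in enumerate(subject_seqs):
        sid = f"S{si + 1:03d}"
        day_seqs = seq.spawn(config.n_days + 1)
        srng = np.random.default_rng(day_seqs[0])
        demo_rows.append(_draw_demographics(srng, sid))
        b = {o: float(srng.normal(0.0, config.subject_sd[o])) for o in OUTCOMES}

        for di in range(config.n_days):
            rng = np.random.default_rng(day_seqs[di + 1])
            date = start + pd.Timedelta(days=di)
            dow = dow_of(date)
            events, bouts, low_wear = generate_day_events(sid, date, config, rng)
            all_events.extend(events)
            idx = true_indices(bouts, config.x_min)

            latent = {}
            for o, base in (("median_rt", config.rt_baseline), ("mean_correct", config.accuracy_baseline)):
                latent[o] = (
                    base
                    + b[o]
                    + _planted_effect(config, o, dow, idx)
                    + float(rng.normal(0.0, config.residual_sd[o]))
                )
            latent["median_rt"] = max(latent["median_rt"], 300.0)
            latent["mean_correct"] = float(np.clip(latent["mean_correct"], 0.0, config.trials_per_session))

            # semi-random prompts ~2.5 h apart inside the wake window
            for k in range(config.prompts_per_day):
                if rng.random() >= config.compliance:
                    continue
                t_h = config.wake_start + 0.75 + 2.5 * k + float(rng.uniform(-0.5, 0.5))
                t_h = float(np.clip(t_h, config.wake_start, config.wake_end - 0.1))
                session_start = date + pd.Timedelta(hours=t_h)
                all_trials.extend(
                    generate_session_trials(
                        latent["median_rt"], latent["mean_correct"], config, rng, sid, session_start
                    )
                )

            row = {
                "subject_id": sid,
                "date": date.date(),
                "dow": dow,
                "low_wear": low_wear,
                "true_rt": latent["median_rt"],
                "true_correct": latent["mean_correct"],
            }
            for cls in BOUT_CLASSES:
                a, g, n = idx[cls]
                row[f"alpha_{cls.lower()}"] = a
                row[f"gini_{cls.lower()}"] = g
                row[f"n_bouts_{cls.lower()}"] = n
            truth_rows.append(row)

    events_df = pd.DataFrame(all_events, columns=["subject_id", "start", "duration_s", "posture", "met"])
    trial_cols = ["subject_id", "session_start", "trial_index", "rt_ms", "correct"]
    trials_df = pd.DataFrame(all_trials, columns=trial_cols)
    truth = {
        "planted_beta_gini": config.planted_beta_gini,
        "planted_beta_alpha": config.planted_beta_alpha,
        "day_truth": pd.DataFrame(truth_rows),
        "icc": {o: config.icc(o) for o in OUTCOMES},
    }
    return SyntheticCohort(
        events=events_df,
        trials=trials_df,
        demographics=pd.DataFrame(demo_rows),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Vectorised day-level fast path


def _grouped_alpha(lengths, gid, counts, x_min):
    logsum = np.bincount(gid, weights=np.log(lengths / x_min), minlength=counts.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = 1.0 + counts / logsum
    alpha[(counts == 0) | (logsum <= 0)] = np.nan
    return alpha


def _grouped_gini(lengths, gid, counts):
    """Sorted-Lorenz Gini per group via segmented cumulative sums."""
    n_groups = counts.size
    order = np.lexsort((lengths, gid))
    x = lengths[order]
    g = gid[order]
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    rank1 = np.arange(x.size) - starts[g] + 1  # 1-based rank within group
    contrib = (2 * rank1 - counts[g] - 1) * x
    num = np.bincount(g, weights=contrib, minlength=n_groups)
    tot = np.bincount(g, weights=x, minlength=n_groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        gini = num / (counts * tot)
    gini[counts == 0] = np.nan
    return np.maximum(gini, 0.0)


def simulate_dow_table(config: SimConfig, seed: int | None = None, aggregation: str = "pool"):
    """Day-level shortcut: draw bouts and outcomes directly, skip event tiling.

    Produces an analysis table with the same schema as
    :func:`boutcog.qc.build_analysis_table` (one row per subject x day of
    week, indices aggregated over that dow's valid days by ``aggregation``
    as in :func:`boutcog.indices.dow_indices`) plus a truth dict.
    Trial-level measurement noise is approximated analytically: the day RT
    gets Gaussian noise with the median standard error of the pooled
    accurate-trial sample, and the day accuracy is binomial.  Days with no
    answered prompt or an injected low-wear flag are dropped, as QC would.

    Because outcomes are driven by each *day's* realized indices, pooling
    bouts across the two same-dow days leaves sampling noise in the
    regressor and attenuates fitted index coefficients (errors in
    variables); ``aggregation="per_day_mean"`` regresses on the average of
    the daily indices instead, which is the exact quantity in the outcome
    model and therefore the right mode for coefficient-recovery studies.
    """
    if aggregation not in ("pool", "per_day_mean"):
        raise ValueError(f"unknown aggregation mode {aggregation!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    nS, nD = config.n_subjects, config.n_days
    n_day = nS * nD
    day_idx = np.tile(np.arange(nD), nS)
    subj_idx = np.repeat(np.arange(nS), nD)
    start = pd.Timestamp(config.start_date)
    dow0 = dow_of(start) - 1
    dow = (dow0 + day_idx) % 7 + 1

    per_cls = {}
    for cls in BOUT_CLASSES:
        counts = rng.poisson(config.bout_count_means[cls], n_day)
        total = int(counts.sum())
        lengths = sample_bout_lengths(config.bout_length_tail[cls], total, rng, config.x_min)
        gid = np.repeat(np.arange(n_day), counts)
        per_cls[cls] = {
            "counts": counts,
            "lengths": lengths,
            "gid": gid,
            "alpha": _grouped_alpha(lengths, gid, counts.astype(float), config.x_min),
            "gini": _grouped_gini(lengths, gid, counts),
        }

    latent = {}
    b_sub = {}
    for o, base in (("median_rt", config.rt_baseline), ("mean_correct", config.accuracy_baseline)):
        b_sub[o] = rng.normal(0.0, config.subject_sd[o], nS)
        eff = np.zeros(n_day)
        for cls in BOUT_CLASSES:
            bg = np.asarray(config.planted_beta_gini[o][cls], dtype=float)[dow - 1]
            ba = np.asarray(config.planted_beta_alpha[o][cls], dtype=float)[dow - 1]
            eff += np.nan_to_num(per_cls[cls]["gini"]) * bg
            eff += np.nan_to_num(per_cls[cls]["alpha"]) * ba
        latent[o] = base + b_sub[o][subj_idx] + eff + rng.normal(0.0, config.residual_sd[o], n_day)
    latent["median_rt"] = np.maximum(latent["median_rt"], 300.0)
    latent["mean_correct"] = np.clip(latent["mean_correct"], 0.0, config.trials_per_session)

    n_sess = rng.binomial(config.prompts_per_day, config.compliance, n_day)
    p_corr = latent["mean_correct"] / config.trials_per_session
    n_corr = rng.binomial(n_sess * config.trials_per_session, p_corr)
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_acc = n_corr / np.maximum(n_sess, 1)
    rt_se = _MEDIAN_SE_FACTOR * config.rt_sigma * latent["median_rt"] / np.sqrt(np.maximum(n_corr, 1))
    obs_rt = latent["median_rt"] + rng.normal(0.0, 1.0, n_day) * rt_se

    low_wear = rng.random(n_day) < config.low_wear_prob
    valid = (n_sess > 0) & ~low_wear

    # collapse to (subject, dow)
    gid2_day = subj_idx * 7 + (dow - 1)
    n_g2 = nS * 7
    vcount = np.bincount(gid2_day, weights=valid.astype(float), minlength=n_g2)
    with np.errstate(divide="ignore", invalid="ignore"):
        y_rt = np.bincount(gid2_day, weights=np.where(valid, obs_rt, 0.0), minlength=n_g2) / vcount
        y_acc = np.bincount(gid2_day, weights=np.where(valid, obs_acc, 0.0), minlength=n_g2) / vcount

    cols = {}
    for cls in BOUT_CLASSES:
        d = per_cls[cls]
        bout_valid = valid[d["gid"]]
        gid2 = gid2_day[d["gid"]][bout_valid]
        x = d["lengths"][bout_valid]
        order_counts = np.bincount(gid2, minlength=n_g2)
        if aggregation == "pool":
            alpha2 = _grouped_alpha(x, gid2, order_counts.astype(float), config.x_min)
            gini2 = _grouped_gini(x, gid2, order_counts)
        else:  # mean of the per-day indices over the dow's valid days
            alpha2 = np.full(n_g2, np.nan)
            gini2 = np.full(n_g2, np.nan)
            for arr, day_vals in ((alpha2, d["alpha"]), (gini2, d["gini"])):
                good = valid & np.isfinite(day_vals)
                cnt = np.bincount(gid2_day[good], minlength=n_g2)
                tot = np.bincount(gid2_day[good], weights=day_vals[good], minlength=n_g2)
                nz = cnt > 0
                arr[nz] = tot[nz] / cnt[nz]
        cols[f"alpha_{cls.lower()}"] = alpha2
        cols[f"gini_{cls.lower()}"] = gini2
        with np.errstate(divide="ignore", invalid="ignore"):
            nb = order_counts / vcount
        cols[f"n_bouts_{cls.lower()}"] = nb

    demo = pd.DataFrame([_draw_demographics(rng, f"S{si + 1:03d}") for si in range(nS)])
    keep = vcount > 0
    sub_of_g2 = np.repeat(np.arange(nS), 7)
    dow_of_g2 = np.tile(np.arange(1, 8), nS)
    tab = pd.DataFrame(
        {
            "subject_id": demo["subject_id"].to_numpy()[sub_of_g2[keep]],
            "dow": dow_of_g2[keep],
            "median_rt": y_rt[keep],
            "mean_correct": y_acc[keep],
            **{k: v[keep] for k, v in cols.items()},
        }
    )
    demo_idx = demo.set_index("subject_id")
    tab["age"] = demo_idx["age"].to_numpy()[sub_of_g2[keep]]
    tab["sex"] = demo_idx["sex"].to_numpy()[sub_of_g2[keep]]
    edu = demo_idx["education"].to_numpy()[sub_of_g2[keep]]
    tab["edu_some_college"] = (edu == EDUCATION_LEVELS[1]).astype(int)
    tab["edu_advanced"] = (edu == EDUCATION_LEVELS[2]).astype(int)

    truth = {
        "planted_beta_gini": config.planted_beta_gini,
        "planted_beta_alpha": config.planted_beta_alpha,
        "latent": {o: latent[o].reshape(nS, nD) for o in OUTCOMES},
        "valid": valid.reshape(nS, nD),
        "icc": {o: config.icc(o) for o in OUTCOMES},
    }
    return tab.reset_index(drop=True), truth


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write events/trials/demographics CSVs plus a truth JSON; return paths."""
    import json
    from pathlib import Path

    from .bouts import write_events
    from .cognition import write_trials

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out / "events.csv",
        "trials": out / "trials.csv",
        "demographics": out / "demographics.csv",
        "truth": out / "truth.json",
    }
    write_events(cohort.events, paths["events"])
    write_trials(cohort.trials, paths["trials"])
    cohort.demographics.to_csv(paths["demographics"], index=False, float_format="%.10g")
    day_truth = cohort.truth["day_truth"].copy()
    day_truth["date"] = day_truth["date"].astype(str)
    payload = {
        "planted_beta_gini": cohort.truth["planted_beta_gini"],
        "planted_beta_alpha": cohort.truth["planted_beta_alpha"],
        "icc": cohort.truth["icc"],
        "day_truth": day_truth.to_dict(orient="list"),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1, default=float)
    return {k: str(v) for k, v in paths.items()}
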