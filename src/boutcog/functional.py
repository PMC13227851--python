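"""Day-of-week varying-coefficient regression with subject random intercepts.

The model for a day-level cognitive outcome of subject i on day-of-week d
(1=Sunday .. 7=Saturday) is

    Y_i(d) = beta_0(d) + alpha_i(d) beta_1(d) + G_i(d) beta_2(d)
             + N_i(d) beta_3(d) + Age_i beta_4(d) + Sex_i beta_5(d)
             + Edu_i beta_6(d) + b_i + e_i(d),

a function-on-scalar regression whose domain degenerates to the 7-point
weekly circle.  Each coefficient curve beta_j(d) is expanded in K cyclic
B-splines with its own circulant difference penalty; within-subject
correlation across the week is absorbed by a scalar random intercept b_i.
Smoothing parameters and the intercept-variance ratio are chosen by REML
(profiled Gaussian criterion, coordinate-wise golden-section search on the
log scale).  Pointwise intervals use the Bayesian posterior covariance of
the penalized coefficients; whole-curve hypotheses beta_j(.) = 0 are tested
with a Wald-type statistic on an effective-rank truncation of the curve
covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .basis import cyclic_basis, cyclic_diff_penalty

__all__ = [
    "ModelSpec",
    "CoefficientCurve",
    "FitResult",
    "build_design",
    "fit_model",
    "wald_test",
    "mean_abs_effect",
]

DAYS = np.arange(1, 8)

_LOG10_LAMBDA_BOUNDS = (-6.0, 8.0)
_LOG10_RHO_BOUNDS = (-6.0, 6.0)
_REML_TOL = 1e-8
_MAX_SWEEPS = 15


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one varying-coefficient model.

    ``outcome`` is the day-level cognitive outcome column, ``bout_class``
    selects which class's alpha/Gini/count enter as predictors.  ``basis_dim``
    (K, 3..7) controls curve flexibility; K=7 with ``smoothing="fixed"`` and
    ``fixed_lambda=0`` is the saturated, unpenalized escape hatch.
    """

    outcome: str = "median_rt"
    bout_class: str = "MVPA"
    basis_dim: int = 5
    penalty_order: int = 2
    smoothing: str = "REML"  # REML | GCV | fixed
    fixed_lambda: float | Sequence[float] | None = None
    fixed_rho: float | None = None
    include_random_intercept: bool = True
    standardize: bool = False
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.outcome not in ("median_rt", "mean_correct"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.bout_class not in ("SED", "LPA", "MVPA"):
            raise ValueError(f"unknown bout class {self.bout_class!r}")
        if not 3 <= self.basis_dim <= 7:
            raise ValueError("basis_dim must be in 3..7")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.smoothing not in ("REML", "GCV", "fixed"):
            raise ValueError(f"unknown smoothing selection {self.smoothing!r}")
        if self.smoothing == "fixed" and self.fixed_lambda is None:
            raise ValueError("smoothing='fixed' requires fixed_lambda")


@dataclass
class CoefficientCurve:
    name: str
    values: np.ndarray  # at d = 1..7
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    edf: float
    wald_stat: float
    wald_df: float
    wald_p: float


@dataclass
class FitResult:
    spec: ModelSpec
    curves: dict[str, CoefficientCurve]
    adjusted_r2: float
    residual_variance: float
    ranint_variance: float
    n_obs: int
    n_subjects: int
    edf_total: float
    n_dropped: int
    smoothing_params: dict[str, float]
    reml_score: float
    n_sweeps: int

    def curves_frame(self) -> pd.DataFrame:
        rows = []
        for name, c in self.curves.items():
            for k, d in enumerate(DAYS):
                rows.append(
                    {
                        "term": name,
                        "d": int(d),
                        "estimate": float(c.values[k]),
                        "se": float(c.se[k]),
                        "lo": float(c.lower[k]),
                        "hi": float(c.upper[k]),
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "bout_class": self.spec.bout_class,
            "basis_dim": self.spec.basis_dim,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "n_dropped": self.n_dropped,
            "adjusted_r2": round(self.adjusted_r2, 6),
            "residual_variance": round(self.residual_variance, 6),
            "ranint_variance": round(self.ranint_variance, 6),
            "edf_total": round(self.edf_total, 4),
            "reml_score": round(self.reml_score, 6),
            "smoothing_params": {k: float(f"{v:.6g}") for k, v in self.smoothing_params.items()},
            "curves": {
                name: {
                    "values": [round(float(v), 6) for v in c.values],
                    "se": [round(float(v), 6) for v in c.se],
                    "lower": [round(float(v), 6) for v in c.lower],
                    "upper": [round(float(v), 6) for v in c.upper],
                    "edf": round(c.edf, 4),
                    "wald_stat": round(c.wald_stat, 6),
                    "wald_df": c.wald_df,
                    "wald_p": float(f"{c.wald_p:.6g}"),
                }
                for name, c in self.curves.items()
            },
        }


def _term_columns(spec: ModelSpec) -> list[tuple[str, str | None]]:
    cls = spec.bout_class.lower()
    return [
        ("intercept", None),
        ("alpha", f"alpha_{cls}"),
        ("gini", f"gini_{cls}"),
        ("n_bouts", f"n_bouts_{cls}"),
        ("age", "age"),
        ("sex", "sex"),
        ("edu_some_college", "edu_some_college"),
        ("edu_advanced", "edu_advanced"),
    ]


@dataclass
class Design:
    X: np.ndarray
    y: np.ndarray
    subject_codes: np.ndarray  # int codes, -1 never present
    subject_ids: np.ndarray
    terms: list[str]
    slices: list[slice]
    penalties: list[np.ndarray]
    B7: np.ndarray  # basis evaluated at d = 1..7
    n_dropped: int


def build_design(observations: pd.DataFrame, spec: ModelSpec) -> Design:
    """Row-wise product of each covariate with the cyclic basis at its dow.

    Rows missing the outcome or any required covariate are dropped (the count
    is kept on the returned design).  Degenerate constant covariates only
    warn: the penalty regularizes the fit.
    """
    terms = _term_columns(spec)
    needed = [spec.outcome] + [col for _, col in terms if col is not None]
    df = observations.copy()
    mask = df[needed].notna().all(axis=1)
    n_dropped = int((~mask).sum())
    df = df[mask]
    if len(df) == 0:
        raise ValueError("no complete observations left after dropping missing rows")

    K = spec.basis_dim
    B = cyclic_basis(df["dow"].to_numpy(dtype=float), K)
    covars = []
    for name, col in terms:
        v = np.ones(len(df)) if col is None else df[col].to_numpy(dtype=float)
        if col is not None and spec.standardize and name not in ("sex", "edu_some_college", "edu_advanced"):
            sd = v.std()
            v = (v - v.mean()) / sd if sd > 0 else v - v.mean()
        if col is not None and np.ptp(v) == 0:
            warnings.warn(f"covariate {name!r} is constant; penalty will regularize", stacklevel=2)
        covars.append(v)

    X = np.concatenate([v[:, None] * B for v in covars], axis=1)
    S = cyclic_diff_penalty(K, spec.penalty_order)
    slices = [slice(i * K, (i + 1) * K) for i in range(len(terms))]
    subj, subj_ids = pd.factorize(df["subject_id"], sort=True)
    return Design(
        X=X,
        y=df[spec.outcome].to_numpy(dtype=float),
        subject_codes=subj,
        subject_ids=np.asarray(subj_ids),
        terms=[name for name, _ in terms],
        slices=slices,
        penalties=[S.copy() for _ in terms],
        B7=cyclic_basis(DAYS.astype(float), K),
        n_dropped=n_dropped,
    )


class _PenalizedLMM:
    """Profiled REML machinery for X beta + Z b with per-term penalties.

    Works with cross-products only; the random-intercept block is eliminated
    analytically (Z'Z is diagonal), so each criterion evaluation costs one
    p x p Cholesky.
    """

    def __init__(self, design: Design, include_ri: bool):
        X, y = design.X, design.y
        self.design = design
        self.include_ri = include_ri
        self.n, self.p = X.shape
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.rank_pen = design.penalties[0].shape[0] - 1  # K - 1 each
        self.n_null = len(design.terms)  # one constant direction per term
        if include_ri:
            codes = design.subject_codes
            self.m = int(codes.max()) + 1
            self.ZtZ = np.bincount(codes, minlength=self.m).astype(float)
            self.Zty = np.bincount(codes, weights=y, minlength=self.m)
            # X'Z: sum rows of X per subject
            XtZ = np.zeros((self.p, self.m))
            np.add.at(XtZ.T, codes, X)
            self.XtZ = XtZ
        else:
            self.m = 0

    def _S(self, lam: np.ndarray) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        for lj, sl, Sj in zip(lam, self.design.slices, self.design.penalties):
            S[sl, sl] += lj * Sj
        return S

    def solve(self, lam: np.ndarray, rho: float | None):
        S = self._S(lam)
        if self.include_ri and rho is not None and rho > 0:
            w = 1.0 / (self.ZtZ + 1.0 / rho)
            XtZw = self.XtZ * w
            M = self.XtX + S - XtZw @ self.XtZ.T
            r = self.Xty - self.XtZ @ (w * self.Zty)
            extra = float(np.sum(w * self.Zty**2))
            logdet_z = float(np.sum(np.log(self.ZtZ + 1.0 / rho)))
        else:
            w = None
            M = self.XtX + S
            r = self.Xty
            extra = 0.0
            logdet_z = 0.0
        # jitter only if needed (lam = 0 saturated case can be borderline)
        try:
            cho = cho_factor(M, lower=True)
        except np.linalg.LinAlgError:
            cho = cho_factor(M + 1e-10 * np.trace(M) / self.p * np.eye(self.p), lower=True)
        beta = cho_solve(cho, r)
        rsspen = max(self.yty - float(beta @ r) - extra, 1e-300)
        logdet_M = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        return beta, cho, w, rsspen, logdet_M + logdet_z

    def reml(self, lam: np.ndarray, rho: float | None) -> float:
        _, _, _, rsspen, logdet_A = self.solve(lam, rho)
        n_eff = self.n - self.n_null
        sigma2 = rsspen / n_eff
        logdet_Gp = float(np.sum(self.rank_pen * np.log(lam)))
        if self.include_ri and rho is not None:
            logdet_Gp += -self.m * np.log(rho)
        return n_eff * np.log(sigma2) + logdet_A - logdet_Gp


def _coordinate_descent(work: _PenalizedLMM, n_terms: int, with_rho: bool):
    log_lam = np.zeros(n_terms)
    log_rho = 0.0
    best = work.reml(10.0**log_lam, 10.0**log_rho if with_rho else None)
    sweeps = 0
    for sweep in range(_MAX_SWEEPS):
        sweeps = sweep + 1
        prev = best
        for j in range(n_terms):
            def f(x, j=j):
                ll = log_lam.copy()
                ll[j] = x
                return work.reml(10.0**ll, 10.0**log_rho if with_rho else None)

            res = minimize_scalar(f, bounds=_LOG10_LAMBDA_BOUNDS, method="bounded",
                                  options={"xatol": 1e-3})
            if res.fun < best:
                log_lam[j], best = res.x, res.fun
        if with_rho:
            def g(x):
                return work.reml(10.0**log_lam, 10.0**x)

            res = minimize_scalar(g, bounds=_LOG10_RHO_BOUNDS, method="bounded",
                                  options={"xatol": 1e-3})
            if res.fun < best:
                log_rho, best = res.x, res.fun
        if abs(prev - best) < _REML_TOL:
            break
    return 10.0**log_lam, (10.0**log_rho if with_rho else None), best, sweeps


def _moment_icc_ratio(design: Design) -> float:
    """Moment estimator of var(b)/var(e) from OLS residuals (one-way ANOVA)."""
    X, y, codes = design.X, design.y, design.subject_codes
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    m = int(codes.max()) + 1
    cnt = np.bincount(codes, minlength=m).astype(float)
    means = np.bincount(codes, weights=r, minlength=m) / np.maximum(cnt, 1)
    ssw = float(np.sum((r - means[codes]) ** 2))
    msw = ssw / max(len(r) - m, 1)
    ssb = float(np.sum(cnt * means**2))
    msb = ssb / max(m - 1, 1)
    nbar = len(r) / m
    sb2 = max((msb - msw) / nbar, 0.0)
    return sb2 / msw if msw > 0 else 0.0


def _gcv_descent(work: _PenalizedLMM, design: Design, n_terms: int, rho: float | None):
    def gcv(lam: np.ndarray) -> float:
        beta, cho, w, _, _ = work.solve(lam, rho)
        rss, edf_terms, edf_ri = _edf_and_rss(work, design, beta, cho, w, rho)
        edf = sum(edf_terms) + edf_ri
        return work.n * rss / (work.n - edf) ** 2

    log_lam = np.zeros(n_terms)
    best = gcv(10.0**log_lam)
    sweeps = 0
    for sweep in range(_MAX_SWEEPS):
        sweeps = sweep + 1
        prev = best
        for j in range(n_terms):
            def f(x, j=j):
                ll = log_lam.copy()
                ll[j] = x
                return gcv(10.0**ll)

            res = minimize_scalar(f, bounds=_LOG10_LAMBDA_BOUNDS, method="bounded",
                                  options={"xatol": 1e-3})
            if res.fun < best:
                log_lam[j], best = res.x, res.fun
        if abs(prev - best) < 1e-8:
            break
    return 10.0**log_lam, best, sweeps


def _edf_and_rss(work, design, beta, cho, w, rho):
    """Unpenalized residual SS plus effective dof split by term and intercepts."""
    X, y, codes = design.X, design.y, design.subject_codes
    if work.include_ri and w is not None:
        b = w * (work.Zty - work.XtZ.T @ beta)
        fitted = X @ beta + b[codes]
    else:
        b = None
        fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))

    if work.include_ri and w is not None:
        M_B = work.XtX - (work.XtZ * w) @ work.XtZ.T
    else:
        M_B = work.XtX
    Minv_MB = cho_solve(cho, M_B)
    diag_fix = np.diag(Minv_MB)
    edf_terms = [float(diag_fix[sl].sum()) for sl in design.slices]
    edf_ri = 0.0
    if work.include_ri and w is not None:
        Minv_XtZ = cho_solve(cho, work.XtZ)
        q = np.einsum("ji,ji->i", work.XtZ, Minv_XtZ)
        edf_ri = float(np.sum(w * work.ZtZ + w**2 * q * work.ZtZ - w * q))
    return rss, edf_terms, edf_ri


def wald_test(theta: np.ndarray, V: np.ndarray) -> tuple[float, int, float]:
    """Wald statistic theta' V^+ theta with rank-aware pseudo-inverse.

    df is the numerical rank of V; a zero-rank covariance yields p = 1 with a
    warning.  Tests H0: the whole coefficient vector is zero.
    """
    theta = np.asarray(theta, dtype=float)
    V = np.asarray(V, dtype=float)
    evals, evecs = np.linalg.eigh((V + V.T) / 2)
    tol = max(evals.max(), 0) * len(evals) * np.finfo(float).eps
    keep = evals > tol
    rank = int(keep.sum())
    if rank == 0:
        warnings.warn("zero-rank covariance in Wald test; p = 1", stacklevel=2)
        return 0.0, 0, 1.0
    proj = evecs[:, keep].T @ theta
    stat = float(np.sum(proj**2 / evals[keep]))
    return stat, rank, float(stats.chi2.sf(stat, rank))


def _curve_wald(values: np.ndarray, Vc: np.ndarray, edf: float, K: int) -> tuple[float, int, float]:
    """Effective-rank truncated Wald test for a fitted coefficient curve.

    The test rank is the term's effective dof rounded to the nearest integer
    (capped by the numerical rank of the curve covariance): under strong
    smoothing a null curve collapses to its unpenalized constant direction,
    and testing only the retained directions keeps the test calibrated.
    """
    evals, evecs = np.linalg.eigh((Vc + Vc.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(evals[0], 0) * len(evals) * np.finfo(float).eps
    rank_max = int(np.sum(evals > tol))
    if rank_max == 0:
        return 0.0, 0, 1.0
    r = int(min(min(rank_max, K), max(1, round(edf))))
    proj = evecs[:, :r].T @ values
    stat = float(np.sum(proj**2 / evals[:r]))
    return stat, r, float(stats.chi2.sf(stat, r))


def mean_abs_effect(curve) -> float:
    """Mean absolute value of a coefficient curve over the seven days."""
    values = curve.values if isinstance(curve, CoefficientCurve) else np.asarray(curve, dtype=float)
    return float(np.mean(np.abs(values)))


def plot_curves(fit: FitResult, path, terms: Sequence[str] = ("gini", "alpha", "n_bouts")) -> None:
    """Estimate-plus-pointwise-band panels over d = 1..7 (one per term)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(terms), figsize=(4 * len(terms), 3.2), sharex=True)
    axes = np.atleast_1d(axes)
    for ax, term in zip(axes, terms):
        c = fit.curves[term]
        ax.fill_between(DAYS, c.lower, c.upper, alpha=0.25)
        ax.plot(DAYS, c.values, marker="o")
        ax.axhline(0.0, ls=":", lw=0.8, color="k")
        ax.set_title(f"{term} (p = {c.wald_p:.3g})")
        ax.set_xlabel("day of week (1 = Sun)")
    axes[0].set_ylabel(f"effect on {fit.spec.outcome}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def fit_model(observations: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit the day-of-week varying-coefficient model to an analysis table.

    Requires at least 10 subjects with 2+ observed days of week each.
    Returns coefficient curves at d = 1..7 with Bayesian pointwise intervals,
    effective-df Wald curve tests, variance components, and adjusted R^2
    (1 - [RSS/(n-edf)] / [TSS/(n-1)]).
    """
    counts = observations.groupby("subject_id")["dow"].nunique()
    if (counts >= 2).sum() < 10:
        raise ValueError("need at least 10 subjects with >= 2 days of week each")

    design = build_design(observations, spec)
    work = _PenalizedLMM(design, spec.include_random_intercept)
    n_terms = len(design.terms)

    if spec.smoothing == "fixed":
        lam = np.asarray(
            np.broadcast_to(np.asarray(spec.fixed_lambda, dtype=float), (n_terms,)), dtype=float
        ).copy()
        if spec.include_random_intercept:
            if spec.fixed_rho is not None:
                rho, score, sweeps = spec.fixed_rho, float("nan"), 0
            else:
                def g(x):
                    return work.reml(np.maximum(lam, 1e-12), 10.0**x)

                res = minimize_scalar(g, bounds=_LOG10_RHO_BOUNDS, method="bounded",
                                      options={"xatol": 1e-4})
                rho, score, sweeps = 10.0**res.x, float(res.fun), 1
        else:
            rho, score, sweeps = None, float("nan"), 0
    elif spec.smoothing == "GCV":
        rho = _moment_icc_ratio(design) if spec.include_random_intercept else None
        if rho is not None and rho <= 0:
            rho = 1e-8
        lam, score, sweeps = _gcv_descent(work, design, n_terms, rho)
    else:  # REML
        lam, rho, score, sweeps = _coordinate_descent(
            work, n_terms, with_rho=spec.include_random_intercept
        )

    beta, cho, w, rsspen, _ = work.solve(lam, rho)
    n_eff = work.n - work.n_null
    sigma2 = rsspen / n_eff
    rss, edf_terms, edf_ri = _edf_and_rss(work, design, beta, cho, w, rho)
    edf_total = float(sum(edf_terms) + edf_ri)

    y = design.y
    tss = float(np.sum((y - y.mean()) ** 2))
    denom = max(work.n - edf_total, 1.0)
    adj_r2 = 1.0 - (rss / denom) / (tss / (work.n - 1))

    Vbeta = sigma2 * cho_solve(cho, np.eye(work.p))
    z = stats.norm.ppf(0.5 + spec.ci_level / 2)
    B7 = design.B7
    curves: dict[str, CoefficientCurve] = {}
    for name, sl, edf_j in zip(design.terms, design.slices, edf_terms):
        theta = beta[sl]
        Vj = Vbeta[sl, sl]
        vals = B7 @ theta
        Vc = B7 @ Vj @ B7.T
        se = np.sqrt(np.maximum(np.diag(Vc), 0.0))
        stat, df, p = _curve_wald(vals, Vc, edf_j, spec.basis_dim)
        curves[name] = CoefficientCurve(
            name=name, values=vals, se=se, lower=vals - z * se, upper=vals + z * se,
            edf=float(edf_j), wald_stat=stat, wald_df=df, wald_p=p,
        )

    smoothing_params = {f"lambda_{t}": float(l) for t, l in zip(design.terms, lam)}
    if rho is not None:
        smoothing_params["rho"] = float(rho)
    return FitResult(
        spec=spec,
        curves=curves,
        adjusted_r2=float(adj_r2),
        residual_variance=float(sigma2),
        ranint_variance=float(sigma2 * rho) if rho is not None else 0.0,
        n_obs=int(work.n),
        n_subjects=int(observations["subject_id"].nunique()),
        edf_total=edf_total,
        n_dropped=design.n_dropped,
        smoothing_params=smoothing_params,
        reml_score=float(score),
        n_sweeps=int(sweeps),
    )
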