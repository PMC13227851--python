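"""Monte-Carlo power for the day-nested-in-subject random-intercept design.

Outcomes are generated as y_ij = b_i + beta * x_ij + e_ij with a
standard-normal day-level covariate x, var(b)/[var(b)+var(e)] equal to the
target intraclass correlation and total variance 1, so beta is a
standardized effect size.  Each simulated dataset is fitted with a Gaussian
random-intercept model (REML over the variance ratio, profiled scale) and
the slope's Wald p-value is compared to the nominal level; power is the
rejection proportion with its Monte-Carlo standard error.

The fitter is a purpose-built profiled-likelihood implementation (the
variance ratio is the only free parameter after profiling, so each fit is a
one-dimensional bounded search over cheap sufficient statistics); it is
cross-checked against statsmodels MixedLM in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = ["PowerConfig", "PowerResult", "fit_random_intercept", "simulate_power", "power_table"]


@dataclass(frozen=True)
class PowerConfig:
    n_subjects: int = 87
    days_per_subject: int = 14
    icc_grid: tuple = (0.3, 0.5, 0.7)
    beta_grid: tuple = (0.0, 0.05, 0.07, 0.10)
    n_sims: int = 500
    alpha_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.icc_grid or not self.beta_grid:
            raise ValueError("grids must be non-empty")
        if any(not 0 <= i < 1 for i in self.icc_grid):
            raise ValueError("ICC values must lie in [0, 1)")
        if self.n_sims < 100:
            raise ValueError("need n_sims >= 100 for reported cells")


@dataclass
class PowerResult:
    table: pd.DataFrame  # columns icc, beta, power, mcse, n_sims, n_singular
    config: PowerConfig


def fit_random_intercept(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    """REML fit of y = a + b*x + subject intercept; returns (b, se, p, ok).

    Profiles the residual scale and searches the variance ratio
    phi = var(b_i)/var(e) on the log scale.  GLS solves use per-group
    sufficient statistics only.
    """
    groups = np.asarray(groups)
    m = int(groups.max()) + 1
    n = y.size
    cnt = np.bincount(groups, minlength=m).astype(float)
    sx = np.bincount(groups, weights=x, minlength=m)
    sy = np.bincount(groups, weights=y, minlength=m)
    sxx = float(x @ x)
    sxy = float(x @ y)
    syy = float(y @ y)
    s1 = float(n)
    sx_tot = float(x.sum())
    sy_tot = float(y.sum())

    def gls(phi: float):
        # V^-1 = I - c_i/n_i J per group, c_i = phi n_i/(1 + phi n_i)
        c = phi / (1.0 + phi * cnt)
        a11 = s1 - float(np.sum(c * cnt * cnt))
        a12 = sx_tot - float(np.sum(c * cnt * sx))
        a22 = sxx - float(np.sum(c * sx * sx))
        b1 = sy_tot - float(np.sum(c * cnt * sy))
        b2 = sxy - float(np.sum(c * sx * sy))
        det = a11 * a22 - a12 * a12
        if det <= 0:
            return None
        beta0 = (a22 * b1 - a12 * b2) / det
        beta1 = (a11 * b2 - a12 * b1) / det
        quad = (
            syy
            - float(np.sum(c * sy * sy))
            - beta0 * b1
            - beta1 * b2
        )
        return beta0, beta1, quad, a11, a22, det

    def neg2reml(logphi: float) -> float:
        phi = np.exp(logphi)
        res = gls(phi)
        if res is None:
            return np.inf
        _, _, quad, _, _, det = res
        if quad <= 0:
            return np.inf
        sigma2 = quad / (n - 2)
        logdet_v = float(np.sum(np.log1p(phi * cnt)))
        return (n - 2) * np.log(sigma2) + logdet_v + np.log(det)

    opt = minimize_scalar(neg2reml, bounds=(-12.0, 8.0), method="bounded", options={"xatol": 1e-6})
    # compare against the boundary phi -> 0 (plain OLS)
    if not np.isfinite(opt.fun):
        return np.nan, np.nan, np.nan, False
    phi = float(np.exp(opt.x))
    if neg2reml(-30.0) < opt.fun:
        phi = 0.0
    res = gls(phi)
    if res is None or res[2] <= 0:
        return np.nan, np.nan, np.nan, False
    _, beta1, quad, a11, _a22, det = res
    sigma2 = quad / (n - 2)
    se = float(np.sqrt(sigma2 * a11 / det))
    z = beta1 / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(beta1), se, p, True


def simulate_power(config: PowerConfig) -> PowerResult:
    """Rejection proportion for each (icc, beta) cell of the design grid.

    Singular or failed fits are counted; cells with more than 1% failures
    raise, otherwise failures are excluded from the denominator.
    """
    rng = np.random.default_rng(config.seed)
    nS, nD = config.n_subjects, config.days_per_subject
    groups = np.repeat(np.arange(nS), nD)
    rows = []
    for icc in config.icc_grid:
        sb = np.sqrt(icc)
        se_ = np.sqrt(1.0 - icc)
        for beta in config.beta_grid:
            rej = 0
            n_ok = 0
            n_singular = 0
            for _ in range(config.n_sims):
                x = rng.standard_normal(nS * nD)
                b = rng.normal(0.0, sb, nS)
                y = b[groups] + beta * x + rng.normal(0.0, se_, nS * nD)
                _bh, _se, p, ok = fit_random_intercept(y, x, groups)
                if not ok:
                    n_singular += 1
                    continue
                n_ok += 1
                if p < config.alpha_level:
                    rej += 1
            if n_singular > 0.01 * config.n_sims:
                raise RuntimeError(
                    f"{n_singular}/{config.n_sims} singular fits at icc={icc}, beta={beta}"
                )
            prop = rej / n_ok if n_ok else float("nan")
            rows.append(
                {
                    "icc": icc,
                    "beta": beta,
                    "power": prop,
                    "mcse": float(np.sqrt(prop * (1 - prop) / n_ok)) if n_ok else float("nan"),
                    "n_sims": n_ok,
                    "n_singular": n_singular,
                }
            )
    return PowerResult(table=pd.DataFrame(rows), config=config)


def power_table(result: PowerResult) -> pd.DataFrame:
    """Pivot to the reporting shape: rows = ICC, columns = beta, cells = power."""
    return result.table.pivot(index="icc", columns="beta", values="power").round(3)
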