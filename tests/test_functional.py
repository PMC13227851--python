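"""Design construction, penalized REML fit, Wald tests, and fit invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import boutcog as bc
from boutcog.functional import build_design, wald_test, mean_abs_effect

from conftest import null_config

TERMS = ["intercept", "alpha", "gini", "n_bouts", "age", "sex", "edu_some_college", "edu_advanced"]
COLS = ["alpha_mvpa", "gini_mvpa", "n_bouts_mvpa", "age", "sex", "edu_some_college", "edu_advanced"]


def test_design_dimensions_and_row_oracle(dow_table_300):
    tab, _ = dow_table_300
    spec = bc.ModelSpec(outcome="median_rt", bout_class="MVPA", basis_dim=5)
    design = build_design(tab, spec)
    assert design.X.shape[1] == 8 * 5  # 8 covariates x K columns
    # hand-assembled product for an arbitrary complete row
    complete = tab.dropna(subset=COLS + ["median_rt"]).reset_index(drop=True)
    row = complete.iloc[13]
    brow = bc.cyclic_basis(float(row["dow"]), 5)
    expected = np.concatenate([v * brow for v in [1.0] + [float(row[c]) for c in COLS]])
    assert np.allclose(design.X[13], expected, atol=1e-12)


def test_dropping_missing_rows_counted(dow_table_300):
    tab, _ = dow_table_300
    tab = tab.copy()
    tab.loc[tab.index[:5], "gini_mvpa"] = np.nan
    design = build_design(tab, bc.ModelSpec(bout_class="MVPA"))
    assert design.n_dropped >= 5


def test_saturated_unpenalized_fit_equals_stratified_ols(dow_table_300):
    """K=7, zero penalty, no random intercept reduces to per-dow OLS."""
    tab, _ = dow_table_300
    spec = bc.ModelSpec(
        outcome="median_rt", bout_class="MVPA", basis_dim=7,
        smoothing="fixed", fixed_lambda=0.0, include_random_intercept=False,
    )
    fit = bc.fit_model(tab, spec)
    for di, d in enumerate(range(1, 8)):
        sub = tab[tab.dow == d].dropna(subset=COLS + ["median_rt"])
        X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(float) for c in COLS])
        beta, *_ = np.linalg.lstsq(X, sub["median_rt"].to_numpy(float), rcond=None)
        for ti, term in enumerate(TERMS):
            assert fit.curves[term].values[di] == pytest.approx(beta[ti], abs=1e-6)


def test_fixed_smoothing_no_ri_is_penalized_least_squares(dow_table_300):
    """With lambda fixed and the intercept variance at zero, the solution is
    the closed-form ridge-type estimate (X'X + S)^-1 X'y."""
    tab, _ = dow_table_300
    lam = 3.7
    spec = bc.ModelSpec(
        outcome="median_rt", bout_class="MVPA", basis_dim=5,
        smoothing="fixed", fixed_lambda=lam, include_random_intercept=False,
    )
    fit = bc.fit_model(tab, spec)
    design = build_design(tab, spec)
    S = np.zeros((40, 40))
    for sl, Sj in zip(design.slices, design.penalties):
        S[sl, sl] += lam * Sj
    beta = np.linalg.solve(design.X.T @ design.X + S, design.X.T @ design.y)
    for ti, (term, sl) in enumerate(zip(design.terms, design.slices)):
        assert np.allclose(fit.curves[term].values, design.B7 @ beta[sl], atol=1e-8)


def test_refuses_insufficient_subjects():
    tab, _ = bc.simulate_dow_table(null_config(n_subjects=5), seed=0)
    with pytest.raises(ValueError, match="10 subjects"):
        bc.fit_model(tab, bc.ModelSpec())


def test_wald_test_contract():
    stat, df, p = wald_test(np.zeros(4), np.eye(4))
    assert stat == 0.0 and p == 1.0 and df == 4
    # scalar case: chi-square(1) equals squared z
    theta, se = np.array([1.7]), 0.6
    stat, df, p = wald_test(theta, np.array([[se**2]]))
    assert stat == pytest.approx((1.7 / se) ** 2)
    assert df == 1
    assert p == pytest.approx(2 * stats.norm.sf(1.7 / se), rel=1e-10)
    with pytest.warns(UserWarning, match="zero-rank"):
        stat, df, p = wald_test(np.ones(3), np.zeros((3, 3)))
    assert p == 1.0


def test_curve_wald_agrees_with_lr_route_on_null_data():
    """On null cohorts the Wald curve statistic tracks the likelihood-ratio
    statistic of dropping the Gini term from the saturated per-dow model."""
    spec = bc.ModelSpec(
        outcome="median_rt", bout_class="MVPA", basis_dim=7,
        smoothing="fixed", fixed_lambda=0.0, include_random_intercept=False,
    )
    diffs, rej_w, rej_lr, n_rep = [], 0, 0, 60
    for k in range(n_rep):
        tab, _ = bc.simulate_dow_table(null_config(n_subjects=80), seed=40_000 + k)
        complete = tab.dropna(subset=COLS + ["median_rt"])
        fit = bc.fit_model(complete, spec)
        c = fit.curves["gini"]
        # LR route: stratified OLS with and without gini, pooled over dows
        lr = 0.0
        for d in range(1, 8):
            sub = complete[complete.dow == d]
            y = sub["median_rt"].to_numpy(float)
            X1 = np.column_stack([np.ones(len(sub))] + [sub[c_].to_numpy(float) for c_ in COLS])
            X0 = np.delete(X1, 1 + COLS.index("gini_mvpa"), axis=1)
            r1 = y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]
            r0 = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
            lr += len(y) * np.log((r0 @ r0) / (r1 @ r1))
        diffs.append(abs(c.wald_stat - lr))
        rej_w += c.wald_p < 0.05
        rej_lr += stats.chi2.sf(lr, 7) < 0.05
    assert np.mean(diffs) < 1.5  # same statistic up to O(1/n)
    assert abs(rej_w - rej_lr) / n_rep <= 3 * np.sqrt(0.05 * 0.95 / n_rep)


def test_mean_abs_effect():
    assert mean_abs_effect(np.zeros(7)) == 0.0
    assert mean_abs_effect(np.full(7, -2.0)) == pytest.approx(2.0)
    vals = np.array([1.0, -3.0, 2.0, 0.0, -1.0, 4.0, -2.0])
    assert mean_abs_effect(vals) == pytest.approx(np.abs(vals).mean())


def test_sex_recoding_invariance_in_saturated_fit(dow_table_300):
    tab, _ = dow_table_300
    spec = bc.ModelSpec(
        outcome="median_rt", bout_class="MVPA", basis_dim=7,
        smoothing="fixed", fixed_lambda=0.0, include_random_intercept=False,
    )
    fit01 = bc.fit_model(tab, spec)
    recoded = tab.copy()
    recoded["sex"] = recoded["sex"] + 1  # 1/2 coding
    fit12 = bc.fit_model(recoded, spec)
    for term in TERMS:
        if term == "intercept":
            shift = fit01.curves["intercept"].values - fit01.curves["sex"].values
            assert np.allclose(fit12.curves[term].values, shift, atol=1e-5)
        else:
            assert np.allclose(fit12.curves[term].values, fit01.curves[term].values, atol=1e-5)


def test_adjusted_r2_increases_with_planted_effect():
    from boutcog.simulate import _zero_curves

    r2 = []
    for c in (0.0, 400.0, 800.0):
        bg = _zero_curves()
        bg["median_rt"]["MVPA"] = (-c,) * 7
        cfg = null_config(n_subjects=250, planted_beta_gini=bg)
        tab, _ = bc.simulate_dow_table(cfg, seed=77, aggregation="per_day_mean")
        fit = bc.fit_model(tab, bc.ModelSpec(outcome="median_rt", bout_class="MVPA"))
        r2.append(fit.adjusted_r2)
    assert r2[0] < r2[1] < r2[2]


def test_reml_recovers_variance_components():
    rng = np.random.default_rng(0)
    nS, sb, se_ = 250, 2.0, 1.0
    rows = []
    b = rng.normal(0, sb, nS)
    for i in range(nS):
        for d in range(1, 8):
            rows.append(
                dict(
                    subject_id=f"S{i:03d}", dow=d,
                    median_rt=10 + b[i] + rng.normal(0, se_),
                    mean_correct=0.0,
                    alpha_mvpa=rng.normal(), gini_mvpa=rng.normal(), n_bouts_mvpa=rng.normal(),
                    age=rng.normal(), sex=int(rng.integers(0, 2)),
                    edu_some_college=int(rng.integers(0, 2)), edu_advanced=0,
                )
            )
    fit = bc.fit_model(pd.DataFrame(rows), bc.ModelSpec())
    assert fit.residual_variance == pytest.approx(se_**2, rel=0.15)
    assert fit.ranint_variance == pytest.approx(sb**2, rel=0.20)
    assert fit.curves["gini"].wald_p > 0.01  # null covariate rarely significant


def test_gcv_mode_runs_and_shrinks_null_curves(dow_table_300):
    tab, _ = dow_table_300
    fit = bc.fit_model(tab, bc.ModelSpec(outcome="median_rt", bout_class="MVPA", smoothing="GCV"))
    # the age effect is null in the generator: GCV should smooth it heavily
    assert fit.curves["age"].edf < 3.0
    assert np.isfinite(fit.adjusted_r2)


def test_plot_curves_writes_figure(tmp_path, dow_table_300):
    from boutcog.functional import plot_curves

    tab, _ = dow_table_300
    fit = bc.fit_model(tab, bc.ModelSpec(outcome="median_rt", bout_class="MVPA"))
    out = tmp_path / "curves.png"
    plot_curves(fit, out)
    assert out.stat().st_size > 0
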