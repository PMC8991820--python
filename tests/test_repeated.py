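"""Repeated-measures estimators: oracle identities, recovery, aggregation."""

import numpy as np
import pandas as pd
import pytest

import ceamiss as cm
from ceamiss.data import Schedule
from ceamiss.repeated import (LongDesign, PointEstimate, RepeatedFit,
                              build_long_design, _fit_rmm_design,
                              _rmm_profile_objective)


def _random_panel(rng, n=30):
    """Small 4-period panel with subject heterogeneity for oracle checks."""
    sched = Schedule(period_boundaries=(0, 4, 8, 13, 17),
                     eq5d_weeks=(0, 6, 13, 17))
    cfg = cm.TrialConfig(
        n_patients=n, seed=int(rng.integers(2 ** 31)), schedule=sched,
        cost_effects=rng.normal(0, 30, 4),
        eq5d_effects={6: 0.02, 13: 0.02, 17: 0.02},
        period_means=(220, 200, 180, 170),
        week_means={0: 0.6, 6: 0.64, 13: 0.66, 17: 0.67},
        subject_sd_cost=50.0, resid_sd_cost=40.0)
    return cm.generate_complete(cfg)


def _lsdv_delta(design: LongDesign) -> pd.Series:
    """Least squares with explicit subject dummies (the within oracle)."""
    tv = [c for c in design.X.columns if c not in design.invariant_cols]
    dummies = pd.get_dummies(design.groups, dtype=float)
    X = np.column_stack([design.X[tv].to_numpy(), dummies.to_numpy()])
    beta, *_ = np.linalg.lstsq(X, design.y, rcond=None)
    return pd.Series(beta[:len(tv)], index=tv)


def test_rmfe_equals_lsdv():
    rng = np.random.default_rng(5)
    for _ in range(5):
        data = _random_panel(rng)
        fit = cm.fit_rmfe(data, "cost")
        oracle = _lsdv_delta(build_long_design(data, "cost"))
        pd.testing.assert_series_equal(fit.params, oracle, atol=1e-8,
                                       rtol=1e-8)


def test_rmfe_invariant_to_absorbed_covariate_shift():
    rng = np.random.default_rng(6)
    data = _random_panel(rng)
    fit1 = cm.fit_rmfe(data, "cost")
    shifted = data.copy()
    shifted.baseline.loc[0, "age"] += 25.0
    fit2 = cm.fit_rmfe(shifted, "cost")
    pd.testing.assert_series_equal(fit1.delta(), fit2.delta(), atol=1e-8,
                                   rtol=1e-8)


def test_rmm_matches_statsmodels_mixedlm():
    """Independent oracle: statsmodels MixedLM on a small panel agrees with
    the profiled-REML fit."""
    from statsmodels.regression.mixed_linear_model import MixedLM
    rng = np.random.default_rng(7)
    data = _random_panel(rng, n=60)
    d = build_long_design(data, "cost")
    ours = _fit_rmm_design(d, "cost", data.schedule)
    sm_fit = MixedLM(d.y, d.X.to_numpy(), groups=d.groups).fit(reml=True)
    np.testing.assert_allclose(ours.params.to_numpy(), sm_fit.fe_params,
                               rtol=1e-4, atol=1e-4)
    assert ours.subject_sd ** 2 == pytest.approx(
        float(np.asarray(sm_fit.cov_re).ravel()[0]), rel=2e-3, abs=1e-2)


def test_rmm_reduces_to_ols_without_heterogeneity():
    cfg = cm.TrialConfig(n_patients=120, seed=11, subject_sd_cost=0.0,
                         subject_sd_eq5d=0.0)
    data = cm.generate_complete(cfg)
    d = build_long_design(data, "eq5d")
    mixed = _fit_rmm_design(d, "eq5d", data.schedule)
    ols, *_ = np.linalg.lstsq(d.X.to_numpy(), d.y, rcond=None)
    scale = np.maximum(np.abs(ols), 1e-3)
    assert np.all(np.abs(mixed.params.to_numpy() - ols) / scale < 1e-2)


def test_rmm_reml_criterion_improves_on_zero_variance(default_trial):
    """The optimised variance ratio cannot do worse than no random effect."""
    d = build_long_design(default_trial, "eq5d")
    X = d.X.to_numpy(float)
    counts = np.bincount(d.groups).astype(float)
    _, objective = _rmm_profile_objective(d.y, X, d.groups, counts, True)
    fit = cm.fit_rmm(default_trial, "eq5d")
    rho_hat = (fit.subject_sd / fit.resid_sd) ** 2
    assert objective(rho_hat) <= objective(0.0) + 1e-6


def test_rmm_balanced_complete_equals_cell_mean_contrasts():
    """Covariate-free balanced design: the interaction estimates equal the
    per-week arm mean differences relative to baseline."""
    cfg = cm.TrialConfig(n_patients=100, seed=13)
    data = cm.generate_complete(cfg)
    d = build_long_design(data, "eq5d")
    keep = [c for c in d.X.columns
            if c in ("intercept", "treat") or c.startswith(("time_",
                                                            "treat_time_"))]
    d2 = LongDesign(y=d.y, X=d.X[keep], groups=d.groups,
                    patient_ids=d.patient_ids, arm=d.arm, times=d.times,
                    delta_names=d.delta_names,
                    invariant_cols=["intercept", "treat"],
                    row_slices=d.row_slices)
    fit = _fit_rmm_design(d2, "eq5d", data.schedule)
    eq = data.eq5d.merge(data.baseline[["patient_id", "treat"]],
                         on="patient_id")
    cell = eq.groupby(["treat", "week"])["utility"].mean().unstack(0)
    diff = cell[1] - cell[0]
    for w in fit.times:
        expected = diff[w] - diff[0]
        assert fit.params[fit.delta_names[w]] == pytest.approx(expected,
                                                               abs=1e-8)


@pytest.mark.parametrize("method", ["rmm", "rmfe"])
def test_recovery_of_true_effects(default_config, default_trial, method):
    """Known-truth simulation: 3-year incremental QALY and cost estimates
    within 3 SE of the generating values."""
    fit_f = cm.fit_rmm if method == "rmm" else cm.fit_rmfe
    fq = fit_f(default_trial, "eq5d")
    fc = fit_f(default_trial, "cost")
    dq = cm.incremental_qaly_total(fq, 3)
    dc = cm.incremental_cost_total(fc, 3)
    assert abs(dq.value - cm.true_incremental_qaly(default_config, 3)) \
        < 3 * dq.se
    assert abs(dc.value - cm.true_incremental_cost(default_config, 3)) \
        < 3 * dc.se


def _fake_cost_fit(deltas, V=None, times=(4.0, 8.0, 13.0)):
    names = {t: f"treat_time_{t:g}" for t in times}
    params = pd.Series({"treat": 0.0,
                        **{names[t]: d for t, d in zip(times, deltas)}})
    if V is None:
        V = np.eye(len(params))
    vcov = pd.DataFrame(V, index=params.index, columns=params.index)
    sched = Schedule(period_boundaries=(0, 4, 8, 13), eq5d_weeks=(0, 4, 13))
    return RepeatedFit(outcome="cost", method="rmm", params=params,
                       vcov=vcov, times=list(times), delta_names=names,
                       beta1_name="treat", absorbed=[], subject_sd=0.0,
                       resid_sd=1.0, n_obs=0, n_subjects=0, schedule=sched)


def test_incremental_cost_sums_coefficients():
    """The quoted three-month rule: total incremental cost = d1 + d2 + d3."""
    fit = _fake_cost_fit([10.0, 20.0, 30.0])
    est = cm.incremental_cost_total(fit, 0.25, rate=0.0)
    assert est.value == pytest.approx(60.0)
    # zero coefficients: variance is the full quadratic form 1'V1
    fit0 = _fake_cost_fit([0.0, 0.0, 0.0])
    est0 = cm.incremental_cost_total(fit0, 0.25, rate=0.0)
    assert est0.value == 0.0 and est0.variance == pytest.approx(3.0)
    # single-period horizon returns the first coefficient and its variance
    est1 = cm.incremental_cost_total(_fake_cost_fit([10.0, 20.0, 30.0]),
                                     4 / 52, rate=0.0)
    assert est1.value == pytest.approx(10.0)
    assert est1.variance == pytest.approx(1.0)


def _fake_eq5d_fit(beta1, deltas, times=(4.0, 13.0)):
    names = {t: f"treat_time_{t:g}" for t in times}
    params = pd.Series({"treat": beta1,
                        **{names[t]: d for t, d in zip(times, deltas)}})
    vcov = pd.DataFrame(np.eye(len(params)), index=params.index,
                        columns=params.index)
    sched = Schedule(period_boundaries=(0, 4, 13), eq5d_weeks=(0, 4, 13))
    return RepeatedFit(outcome="eq5d", method="rmm", params=params,
                       vcov=vcov, times=list(times), delta_names=names,
                       beta1_name="treat", absorbed=[], subject_sd=0.0,
                       resid_sd=1.0, n_obs=0, n_subjects=0, schedule=sched)


def test_incremental_qaly_printed_formula():
    fit = _fake_eq5d_fit(0.0, [0.05, 0.05])
    est = cm.incremental_qaly_total(fit, 0.25, rate=0.0)
    assert est.value == pytest.approx(0.010577, abs=1e-6)
    assert cm.incremental_qaly_total(_fake_eq5d_fit(0.0, [0.0, 0.0]),
                                     0.25).value == 0.0
    doubled = cm.incremental_qaly_total(_fake_eq5d_fit(0.0, [0.1, 0.1]),
                                        0.25, rate=0.0)
    assert doubled.value == pytest.approx(2 * est.value)


def test_incremental_totals_are_linear_in_horizon(default_trial):
    """3-year total = 1-year total + the year-2 and year-3 terms."""
    fit = cm.fit_rmm(default_trial, "cost")
    e1 = cm.incremental_cost_total(fit, 1)
    e3 = cm.incremental_cost_total(fit, 3)
    extra = sum(
        fit.params[fit.delta_names[float(fit.schedule.period_end(t))]]
        * cm.discount_factor(fit.schedule.period_midpoint(t), 0.035)
        for t in (13, 14))
    assert e3.value == pytest.approx(e1.value + extra, rel=1e-10)


def test_bootstrap_determinism_and_consistency(default_trial):
    d1 = cm.bootstrap_cea(default_trial, 3, B=120, seed=3, method="rmfe")
    d2 = cm.bootstrap_cea(default_trial, 3, B=120, seed=3, method="rmfe")
    pd.testing.assert_frame_equal(d1, d2)
    # bootstrap mean consistent with the point estimate
    big = cm.bootstrap_cea(default_trial, 3, B=500, seed=4, method="rmfe")
    fq = cm.fit_rmfe(default_trial, "eq5d")
    point = cm.incremental_qaly_total(fq, 3).value
    mc_se = big["delta_qaly"].std(ddof=1) / np.sqrt(len(big))
    assert abs(big["delta_qaly"].mean() - point) < 3 * mc_se


def test_bootstrap_rejects_small_B(default_trial):
    with pytest.raises(ValueError, match="B must be"):
        cm.bootstrap_cea(default_trial, 3, B=50, seed=1)
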