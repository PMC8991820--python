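"""Bivariate regression, complete-case analysis and the Bayesian selection
model."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import ceamiss as cm
from ceamiss.aggregate import (BpaConfig, bivariate_fit, bpa_fit, cca_fit,
                               draw_missing_totals, split_rhat,
                               _aggregate_design, _drop_empty_and_check_rank)


@pytest.fixture(scope="module")
def complete_agg(complete_trial):
    return cm.assemble_aggregate(complete_trial, 3)


def test_bivariate_equals_per_equation_ols(complete_trial, complete_agg):
    """Shared-regressor SUR identity: the joint fit equals two separate
    least-squares fits, coefficient for coefficient."""
    fit = bivariate_fit(complete_agg, complete_trial)
    X = _aggregate_design(complete_trial,
                          complete_agg["patient_id"].to_numpy())
    for col in ("cost", "qaly"):
        ols = sm.OLS(complete_agg[f"total_{col}"].to_numpy(),
                     X.to_numpy(float)).fit()
        np.testing.assert_allclose(fit.coef[col].to_numpy(), ols.params,
                                   rtol=1e-10, atol=1e-10)
    # and the per-equation standard errors match the Kronecker blocks
    ols_q = sm.OLS(complete_agg["total_qaly"].to_numpy(),
                   X.to_numpy(float)).fit()
    np.testing.assert_allclose(np.sqrt(fit.delta_cov[1, 1]),
                               ols_q.bse[list(X.columns).index("treat")],
                               rtol=1e-10)


def test_bivariate_identical_columns_identical_coefficients(complete_trial,
                                                            complete_agg):
    twin = complete_agg.copy()
    twin["total_qaly"] = twin["total_cost"]
    fit = bivariate_fit(twin, complete_trial)
    np.testing.assert_allclose(fit.coef["cost"], fit.coef["qaly"])


def test_bivariate_independent_residuals_uncorrelated_deltas():
    """Truth with independent cost/QALY noise: the off-diagonal treatment
    covariance is within 3 Monte-Carlo SE of zero (checked via the residual
    correlation it derives from)."""
    cfg = cm.TrialConfig(n_patients=400, seed=61, subject_sd_cost=0.0,
                         subject_sd_eq5d=0.0)
    data = cm.generate_complete(cfg)
    agg = cm.assemble_aggregate(data, 1)
    fit = bivariate_fit(agg, data)
    n = fit.n_used
    r = fit.resid_cov[0, 1] / np.sqrt(fit.resid_cov[0, 0]
                                      * fit.resid_cov[1, 1])
    assert abs(r) < 3 / np.sqrt(n)


def test_singular_design_names_aliased_columns(complete_trial, complete_agg):
    X = _aggregate_design(complete_trial,
                          complete_agg["patient_id"].to_numpy())
    X["dup"] = X["treat"]
    with pytest.raises(np.linalg.LinAlgError, match="aliased"):
        _drop_empty_and_check_rank(X)


def test_cca_on_complete_data_equals_bivariate(complete_trial, complete_agg):
    a = bivariate_fit(complete_agg, complete_trial)
    b = cca_fit(complete_agg, complete_trial)
    np.testing.assert_allclose(a.coef.to_numpy(), b.coef.to_numpy())
    assert b.n_used == len(complete_agg)


def test_cca_count_matches_pattern_table(default_trial):
    agg = cm.assemble_aggregate(default_trial, 3)
    fit = cca_fit(agg, default_trial)
    pt = cm.pattern_table(agg)
    assert fit.n_used == pt.loc[0, "n"]
    assert fit.n_used < default_trial.n_patients


def test_split_rhat_detects_disagreement():
    rng = np.random.default_rng(0)
    same = rng.normal(size=(2, 2000))
    apart = np.stack([rng.normal(0, 1, 2000), rng.normal(5, 1, 2000)])
    assert split_rhat(same) < 1.02
    assert split_rhat(apart) > 2.0


def test_missing_total_conditional_draw_matches_closed_form():
    """Given parameters, a missing total draws from the conditional normal
    given the observed partner outcome."""
    rng = np.random.default_rng(8)
    Sigma = np.array([[2.0, 0.8], [0.8, 1.0]])
    mu = np.tile([1.0, -0.5], (20_000, 1))
    Y = np.tile([np.nan, 0.7], (20_000, 1))
    miss_c = np.ones(20_000, dtype=bool)
    miss_q = np.zeros(20_000, dtype=bool)
    draw_missing_totals(mu, Sigma, Y, miss_c, miss_q, rng)
    want_mean = 1.0 + 0.8 / 1.0 * (0.7 - (-0.5))
    want_var = 2.0 - 0.8 ** 2 / 1.0
    assert Y[:, 0].mean() == pytest.approx(want_mean, abs=0.03)
    assert Y[:, 0].var() == pytest.approx(want_var, abs=0.05)


@pytest.fixture(scope="module")
def bpa_small():
    cfg = cm.TrialConfig(n_patients=150, seed=71)
    data = cm.generate_complete(cfg)
    agg = cm.assemble_aggregate(data, 1)
    return data, agg


def test_bpa_complete_data_concordant_with_bivariate(bpa_small):
    data, agg = bpa_small
    biv = bivariate_fit(agg, data)
    res = bpa_fit(agg, data, BpaConfig(iterations=4000, burn_in=1000,
                                       seed=5))
    mcse = res.mcse()
    tol_c = 4 * mcse[0] + 0.02 * np.sqrt(res.posterior_cov[0, 0])
    tol_q = 4 * mcse[1] + 0.02 * np.sqrt(res.posterior_cov[1, 1])
    assert abs(res.delta_cost - biv.delta_cost) < tol_c
    assert abs(res.delta_qaly - biv.delta_qaly) < tol_q
    assert max(res.rhat.values()) < 1.05


def test_bpa_posterior_widens_with_missingness(bpa_small):
    data, agg = bpa_small
    res_full = bpa_fit(agg, data, BpaConfig(iterations=3000, burn_in=1000,
                                            seed=9))
    masked = agg.copy()
    rng = np.random.default_rng(2)
    drop = rng.random(len(masked)) < 0.4
    masked.loc[drop, "total_qaly"] = np.nan
    masked.loc[drop, "qaly_complete"] = False
    res_miss = bpa_fit(masked, data, BpaConfig(iterations=3000,
                                               burn_in=1000, seed=9))
    assert np.sqrt(res_miss.posterior_cov[1, 1]) \
        > 0.95 * np.sqrt(res_full.posterior_cov[1, 1])
    assert res_miss.n_obs_qaly == int((~drop).sum())


def test_bpa_ignorable_without_missingness_submodel(default_trial):
    """Under MAR with distinct priors the auxiliary logistic submodels do
    not move the outcome posterior (ignorability)."""
    agg = cm.assemble_aggregate(default_trial, 1)
    with_aux = bpa_fit(agg, default_trial,
                       BpaConfig(iterations=2500, burn_in=800, seed=4))
    without = bpa_fit(agg, default_trial,
                      BpaConfig(iterations=2500, burn_in=800, seed=4,
                                include_missingness_model=False))
    sd = np.sqrt(np.diag(with_aux.posterior_cov))
    assert abs(with_aux.delta_cost - without.delta_cost) < 0.2 * sd[0]
    assert abs(with_aux.delta_qaly - without.delta_qaly) < 0.2 * sd[1]


def test_bpa_prior_sensitivity_small(default_trial):
    """Varying the coefficient-prior precision across its vague range moves
    the posterior mean by less than one posterior SD."""
    agg = cm.assemble_aggregate(default_trial, 1)
    lo = bpa_fit(agg, default_trial,
                 BpaConfig(prior_precision=0.001, iterations=2500,
                           burn_in=800, seed=6))
    hi = bpa_fit(agg, default_trial,
                 BpaConfig(prior_precision=0.01, iterations=2500,
                           burn_in=800, seed=6))
    sd = np.sqrt(np.diag(lo.posterior_cov))
    assert abs(lo.delta_cost - hi.delta_cost) < sd[0]
    assert abs(lo.delta_qaly - hi.delta_qaly) < sd[1]


def test_bpa_config_validation():
    with pytest.raises(ValueError, match="exceed burn_in"):
        BpaConfig(iterations=100, burn_in=200)
    with pytest.raises(ValueError, match="chains"):
        BpaConfig(chains=1)
    with pytest.warns(UserWarning, match="vague range"):
        BpaConfig(prior_precision=10.0)
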