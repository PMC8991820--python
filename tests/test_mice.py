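"""Chained-equations imputation and Rubin's-rules pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ceamiss as cm
from ceamiss.mice import pmm_draw, rubin_pool, _wide_tables


@pytest.fixture(scope="module")
def small_mar_trial():
    cfg = cm.TrialConfig(n_patients=200, seed=77)
    return cm.make_trial(cfg)


@pytest.fixture(scope="module")
def completed_pair(small_mar_trial):
    cfg = cm.MiceConfig(M=3, cycles=3, imputer="pmm", seed=5)
    return cm.mice_impute(small_mar_trial, cfg), small_mar_trial


def test_complete_data_returns_identical_copies(complete_trial):
    sets = cm.mice_impute(complete_trial, cm.MiceConfig(M=2, cycles=1,
                                                        seed=1))
    for s in sets:
        pd.testing.assert_frame_equal(
            s.period_costs[["patient_id", "period", "cost"]],
            complete_trial.period_costs[["patient_id", "period", "cost"]])
        pd.testing.assert_frame_equal(
            s.eq5d[["patient_id", "week", "utility"]],
            complete_trial.eq5d[["patient_id", "week", "utility"]])


def test_observed_cells_never_altered(completed_pair):
    sets, data = completed_pair
    obs = data.eq5d[data.eq5d["observed"]]
    for s in sets:
        merged = obs.merge(s.eq5d, on=["patient_id", "week"],
                           suffixes=("", "_imp"))
        assert np.allclose(merged["utility"], merged["utility_imp"])


def test_same_seed_reproduces_completed_sets(small_mar_trial):
    cfg = cm.MiceConfig(M=2, cycles=2, imputer="linreg", seed=9)
    a = cm.mice_impute(small_mar_trial, cfg)
    b = cm.mice_impute(small_mar_trial, cfg)
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x.eq5d, y.eq5d)
        pd.testing.assert_frame_equal(x.period_costs, y.period_costs)


def test_pmm_stays_within_observed_support(completed_pair):
    sets, data = completed_pair
    V, O, keys, _ = _wide_tables(data)
    for s in sets:
        Vc, _, _, _ = _wide_tables(s)
        for j in range(V.shape[1]):
            obs = V[O[:, j], j]
            assert Vc[:, j].min() >= obs.min() - 1e-9
            assert Vc[:, j].max() <= obs.max() + 1e-9


def test_linreg_escapes_observed_support(small_mar_trial):
    """Normal-draw imputation is not bounded by the observed values."""
    sets = cm.mice_impute(small_mar_trial,
                          cm.MiceConfig(M=2, cycles=3, imputer="linreg",
                                        seed=13))
    V, O, keys, _ = _wide_tables(small_mar_trial)
    escaped = 0
    for s in sets:
        Vc, _, _, _ = _wide_tables(s)
        for j in range(V.shape[1]):
            obs = V[O[:, j], j]
            if Vc[:, j].min() < obs.min() or Vc[:, j].max() > obs.max():
                escaped += 1
    assert escaped > 0


def test_pmm_draw_degenerate_and_toy_pool():
    rng = np.random.default_rng(0)
    # noiseless linear truth, k=1, duplicate covariates -> the exact donor
    x = np.arange(10, dtype=float)
    y = 2.0 + 3.0 * x
    X = np.column_stack([np.ones(10), x])
    got = pmm_draw(y, X, X[[4]], k=1, rng=rng)
    assert got[0] == y[4]
    # k=3 mid-range case draws from the three nearest donors
    target = np.array([[1.0, 4.6]])
    draws = {pmm_draw(y, X, target, k=3,
                      rng=np.random.default_rng(s))[0] for s in range(40)}
    # prediction 15.8; nearest predicted values are y=17, 14, 20
    nearest3 = {y[4], y[5], y[6]}
    assert draws <= nearest3 and len(draws) > 1


def test_linreg_zero_residual_gives_prediction():
    cfg = cm.MiceConfig(M=2, cycles=2, imputer="linreg", seed=3)
    # build a deterministic trial then hide one value
    base_cfg = cm.TrialConfig(n_patients=60, seed=41, subject_sd_cost=0.0,
                              subject_sd_eq5d=0.0, resid_sd_cost=0.0,
                              resid_sd_eq5d=0.0)
    data = cm.generate_complete(base_cfg)
    mask = (data.eq5d["patient_id"] == 1) & (data.eq5d["week"] == 26)
    truth = float(data.eq5d.loc[mask, "utility"].iloc[0])
    data.eq5d.loc[mask, "utility"] = np.nan
    data.eq5d.loc[mask, "observed"] = False
    sets = cm.mice_impute(data, cfg)
    for s in sets:
        got = s.eq5d.loc[(s.eq5d["patient_id"] == 1)
                         & (s.eq5d["week"] == 26), "utility"].iloc[0]
        assert got == pytest.approx(truth, abs=1e-6)


def test_precondition_on_observed_cases():
    cfg = cm.TrialConfig(n_patients=30, seed=2)
    data = cm.make_trial(cfg)
    with pytest.raises(ValueError, match="observed cases"):
        cm.mice_impute(data, cm.MiceConfig(M=2, cycles=1))


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def _pool_oracle(est, var):
    """Brute-force arithmetic pooling for a scalar parameter."""
    m = len(est)
    qbar = sum(est) / m
    w = sum(var) / m
    b = sum((e - qbar) ** 2 for e in est) / (m - 1)
    t = w + (1 + 1 / m) * b
    return qbar, w, b, t


def test_rubin_pool_worked_example():
    pooled = rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
    assert pooled.qbar[0] == pytest.approx(2.0)
    assert pooled.W[0, 0] == pytest.approx(1.0)
    assert pooled.B[0, 0] == pytest.approx(1.0)
    assert pooled.T[0, 0] == pytest.approx(2.3333, abs=1e-4)


def test_rubin_pool_matches_bruteforce_oracle():
    rng = np.random.default_rng(12)
    for _ in range(100):
        m = int(rng.integers(2, 12))
        est = rng.normal(size=m)
        var = rng.uniform(0.1, 5.0, size=m)
        q, w, b, t = _pool_oracle(list(est), list(var))
        pooled = rubin_pool(est, var)
        assert abs(pooled.qbar[0] - q) < 1e-10
        assert abs(pooled.W[0, 0] - w) < 1e-10
        assert abs(pooled.B[0, 0] - b) < 1e-10
        assert abs(pooled.T[0, 0] - t) < 1e-10


def test_rubin_pool_identical_estimates_have_no_between_variance():
    pooled = rubin_pool([1.5] * 5, [2.0] * 5)
    assert pooled.B[0, 0] == 0.0
    assert pooled.T[0, 0] == pytest.approx(pooled.W[0, 0])
    assert pooled.fmi[0] == pytest.approx(0.0, abs=1e-9)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(c=st.floats(0.1, 50.0))
def test_rubin_pool_scaling_equivariance(c):
    est = [1.0, 2.0, 4.0]
    var = [1.0, 0.5, 2.0]
    a = rubin_pool(est, var)
    b = rubin_pool([c * e for e in est], [c * c * v for v in var])
    assert b.qbar[0] == pytest.approx(c * a.qbar[0])
    assert b.T[0, 0] == pytest.approx(c * c * a.T[0, 0], rel=1e-9)
    assert b.fmi[0] == pytest.approx(a.fmi[0], rel=1e-9)


def test_rubin_pool_invariants_and_errors():
    rng = np.random.default_rng(3)
    est = rng.normal(size=(8, 2))
    var = np.stack([np.eye(2) * v for v in rng.uniform(0.5, 2, 8)])
    pooled = rubin_pool(est, var)
    np.testing.assert_allclose(pooled.T, pooled.W + (1 + 1 / 8) * pooled.B)
    assert np.all((pooled.fmi >= 0) & (pooled.fmi <= 1))
    assert np.all(pooled.mce >= 0)
    with pytest.raises(ValueError, match="conformable"):
        rubin_pool(est, np.ones((8, 3)))
    with pytest.raises(ValueError, match="at least 2"):
        rubin_pool([1.0], [1.0])


def test_mi_analysis_recovers_truth(default_config, default_trial):
    res = cm.mi_analysis(default_trial,
                         cm.MiceConfig(M=8, cycles=4, imputer="pmm", seed=6),
                         3)
    truth = cm.true_incremental_qaly(default_config, 3)
    assert abs(res.delta_qaly - truth) < 3 * res.pooled.se()[1]
    assert abs(res.delta_cost - 0.0) < 3 * res.pooled.se()[0]
    assert res.n_used == default_trial.n_patients
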