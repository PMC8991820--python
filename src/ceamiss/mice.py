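"""Multiple imputation by chained equations, with Rubin's-rules pooling.

Each longitudinal variable — every period cost and every EQ-5D week — is
imputed conditional on all the other longitudinal variables plus the baseline
predictors, cycling through the variables in schedule order.  Two imputers
are available:

* ``linreg`` — proper Bayesian linear regression: the residual variance is
  drawn from its scaled inverse-chi-square posterior, the coefficients from
  their conditional normal, and the missing value from the resulting
  posterior predictive normal;
* ``pmm`` — type-2 predictive mean matching: predictions for missing cases
  use a posterior coefficient draw, predictions for observed cases the
  least-squares fit, and each missing case receives the observed value of a
  donor drawn uniformly from its k nearest neighbours in predicted value
  (ties at the k-th distance enlarge the pool).

Missing-by-design cells (beyond a patient's follow-up window) are imputed
like any other missing cell: that is precisely how multiple imputation
recovers horizons beyond a patient's own follow-up.  Observed cells are
never altered.

Pooling follows Rubin's rules with Barnard-Rubin degrees of freedom, the
fraction of missing information (FMI), the Monte-Carlo error of the pooled
estimate and the relative efficiency loss at the chosen number of
imputations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .aggregate import FitResult, bivariate_fit
from .data import TrialDataset
from .outcomes import assemble_aggregate

__all__ = ["MiceConfig", "PooledEstimate", "MiResult", "mice_impute",
           "pmm_draw", "estimate_per_dataset", "rubin_pool", "mi_analysis"]

DEFAULT_PREDICTORS = ("treat", "age", "duration", "site", "size",
                      "ethnicity", "diabetes", "dvt_history", "trial_leg")


@dataclass
class MiceConfig:
    """Settings for the chained-equations imputer.

    The baseline EQ-5D enters every imputation model automatically as the
    week-0 longitudinal column (it is never missing), so it is not listed
    among ``predictors``.
    """

    M: int = 40
    cycles: int = 20
    imputer: str = "pmm"            # 'linreg' | 'pmm'
    k_donors: int = 10
    predictors: Sequence[str] = DEFAULT_PREDICTORS
    seed: int = 0

    def __post_init__(self):
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.k_donors < 1:
            raise ValueError("k_donors must be >= 1")
        if self.imputer not in ("linreg", "pmm"):
            raise ValueError("imputer must be 'linreg' or 'pmm'")


# ---------------------------------------------------------------------------
# wide-format scaffolding
# ---------------------------------------------------------------------------

def _wide_tables(data: TrialDataset):
    """Return (values, observed, var_keys, patient order).

    ``var_keys`` lists ('cost', period) / ('eq5d', week) in schedule order
    (earliest first; EQ-5D before a cost period ending the same week).
    """
    sched = data.schedule
    keys = []
    for w in sorted(set([float(x) for x in sched.eq5d_weeks]
                        + [float(sched.period_end(t))
                           for t in range(1, sched.n_periods + 1)])):
        for wk in [x for x in sched.eq5d_weeks if float(x) == w]:
            keys.append(("eq5d", wk))
        for t in range(1, sched.n_periods + 1):
            if float(sched.period_end(t)) == w:
                keys.append(("cost", t))

    pids = data.baseline["patient_id"].to_numpy()
    cost_v = data.period_costs.pivot(index="patient_id", columns="period",
                                     values="cost").reindex(pids)
    cost_o = data.period_costs.pivot(index="patient_id", columns="period",
                                     values="observed").reindex(pids)
    eq_v = data.eq5d.pivot(index="patient_id", columns="week",
                           values="utility").reindex(pids)
    eq_o = data.eq5d.pivot(index="patient_id", columns="week",
                           values="observed").reindex(pids)
    n = len(pids)
    V = np.empty((n, len(keys)))
    O = np.empty((n, len(keys)), dtype=bool)
    for j, (kind, key) in enumerate(keys):
        src_v = cost_v if kind == "cost" else eq_v
        src_o = cost_o if kind == "cost" else eq_o
        V[:, j] = src_v[key].to_numpy(dtype=float)
        O[:, j] = src_o[key].to_numpy(dtype=bool)
    V[~O] = np.nan
    return V, O, keys, pids


def _baseline_design(data: TrialDataset, predictors: Sequence[str]) -> np.ndarray:
    base = data.baseline
    cols = []
    for p in predictors:
        if p == "site":
            for s in sorted(base["site"].unique())[1:]:
                cols.append((base["site"] == s).to_numpy(dtype=float))
        elif p in base.columns:
            cols.append(base[p].to_numpy(dtype=float))
        else:
            raise KeyError(f"predictor '{p}' not in baseline table")
    return np.column_stack(cols) if cols else np.empty((len(base), 0))


def _posterior_beta_draw(Xo: np.ndarray, yo: np.ndarray,
                         rng: np.random.Generator):
    """Proper Bayesian draw for a linear imputation model.

    Returns (beta_ls, beta_draw, sigma_draw, keep) where ``keep`` indexes the
    non-aliased columns of the design (pivoted-QR rank detection).
    """
    n, p = Xo.shape
    Q, R, piv = sla.qr(Xo, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    r = int((diag > tol).sum())
    keep = np.sort(piv[:r])
    Xk = Xo[:, keep]
    Q, R = np.linalg.qr(Xk)
    beta_ls = sla.solve_triangular(R, Q.T @ yo)
    resid = yo - Xk @ beta_ls
    df = max(n - r, 1)
    sse = float(resid @ resid)
    sigma2 = sse / stats.chi2.rvs(df, random_state=rng) if sse > 0 else 0.0
    z = rng.standard_normal(r)
    beta_draw = beta_ls + np.sqrt(sigma2) * sla.solve_triangular(R, z)
    return beta_ls, beta_draw, float(np.sqrt(sigma2)), keep


def pmm_draw(y_obs: np.ndarray, X_obs: np.ndarray, X_mis: np.ndarray,
             k: int, rng: np.random.Generator) -> np.ndarray:
    """Type-2 predictive mean matching.

    Predictions for the missing cases use a posterior coefficient draw,
    predictions for the observed cases the least-squares fit; each missing
    case draws uniformly from the donors whose predicted values are among
    the k nearest (all donors tied at the k-th distance are included).
    """
    if len(y_obs) < k:
        raise ValueError(f"need at least k={k} observed cases for matching")
    beta_ls, beta_draw, _, keep = _posterior_beta_draw(X_obs, y_obs, rng)
    pred_obs = X_obs[:, keep] @ beta_ls
    pred_mis = X_mis[:, keep] @ beta_draw
    if len(pred_mis) == 0:
        return np.empty(0)
    D = np.abs(pred_obs[None, :] - pred_mis[:, None])
    kth = np.partition(D, k - 1, axis=1)[:, k - 1]
    in_pool = D <= kth[:, None] * (1 + 1e-12) + 1e-300
    pool_sizes = in_pool.sum(axis=1)
    pick = (rng.random(len(pred_mis)) * pool_sizes).astype(int)
    # index of the pick-th True per row via cumulative counts
    cum = np.cumsum(in_pool, axis=1)
    donor_col = (cum == (pick + 1)[:, None]).argmax(axis=1)
    return y_obs[donor_col]


def _check_preconditions(O: np.ndarray, keys, k_donors: int) -> None:
    need = max(20, k_donors + 5)
    for j, key in enumerate(keys):
        n_obs = int(O[:, j].sum())
        if n_obs < O.shape[0] and n_obs < need:
            raise ValueError(
                f"variable {key} has only {n_obs} observed cases "
                f"(needs >= {need}); imputation would be unstable")


def mice_impute(data: TrialDataset, cfg: Optional[MiceConfig] = None
                ) -> List[TrialDataset]:
    """Produce M completed datasets by chained-equations imputation."""
    cfg = cfg or MiceConfig()
    V0, O, keys, pids = _wide_tables(data)
    _check_preconditions(O, keys, cfg.k_donors)
    P = _baseline_design(data, cfg.predictors)
    n, nv = V0.shape
    incomplete = [j for j in range(nv) if not O[:, j].all()]
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.M)

    completed: List[TrialDataset] = []
    for m in range(cfg.M):
        rng = np.random.default_rng(seeds[m])
        V = V0.copy()
        # initial fill: simple random sampling from the observed values
        for j in incomplete:
            obs_vals = V0[O[:, j], j]
            V[~O[:, j], j] = rng.choice(obs_vals, size=(~O[:, j]).sum(),
                                        replace=True)
        for _ in range(cfg.cycles):
            for j in incomplete:
                others = [c for c in range(nv) if c != j]
                X = np.column_stack([np.ones(n), V[:, others], P])
                oj = O[:, j]
                if cfg.imputer == "pmm":
                    V[~oj, j] = pmm_draw(V0[oj, j], X[oj], X[~oj],
                                         cfg.k_donors, rng)
                else:
                    _, bdraw, sig, keep = _posterior_beta_draw(
                        X[oj], V0[oj, j], rng)
                    V[~oj, j] = X[~oj][:, keep] @ bdraw \
                        + sig * rng.standard_normal((~oj).sum())
        completed.append(_write_back(data, V, keys, pids))
    return completed


def _write_back(data: TrialDataset, V: np.ndarray, keys, pids) -> TrialDataset:
    out = data.copy()
    out.shadow_costs = None
    out.shadow_eq5d = None
    cost_cols = {key: V[:, j] for j, (kind, key) in enumerate(keys)
                 if kind == "cost"}
    eq_cols = {key: V[:, j] for j, (kind, key) in enumerate(keys)
               if kind == "eq5d"}
    pc = out.period_costs.set_index(["patient_id", "period"])
    for t, vals in cost_cols.items():
        pc.loc[pd.MultiIndex.from_arrays([pids, np.full(len(pids), t)]),
               "cost"] = vals
    pc["observed"] = True
    pc["scheduled"] = True
    out.period_costs = pc.reset_index()
    eq = out.eq5d.set_index(["patient_id", "week"])
    for w, vals in eq_cols.items():
        eq.loc[pd.MultiIndex.from_arrays([pids, np.full(len(pids), w)]),
               "utility"] = vals
    eq["observed"] = True
    eq["scheduled"] = True
    out.eq5d = eq.reset_index()
    return out


# ---------------------------------------------------------------------------
# per-dataset estimation and pooling
# ---------------------------------------------------------------------------

def estimate_per_dataset(completed: TrialDataset, horizon_years: float,
                         rate: float = 0.035, discount_qalys: bool = True,
                         include_eq5d0: bool = True) -> FitResult:
    """Passive totals then the bivariate regression on one completed set."""
    agg = assemble_aggregate(completed, horizon_years, rate=rate,
                             discount_qalys=discount_qalys)
    return bivariate_fit(agg, completed, include_eq5d0=include_eq5d0,
                         method_tag="mi-component")


@dataclass
class PooledEstimate:
    """Rubin-combined estimate across M imputations."""

    qbar: np.ndarray           # pooled coefficient vector (k,)
    W: np.ndarray              # within-imputation covariance (k, k)
    B: np.ndarray              # between-imputation covariance (k, k)
    T: np.ndarray              # total covariance (k, k)
    df: np.ndarray             # Barnard-Rubin dof per coefficient
    fmi: np.ndarray            # fraction of missing information
    mce: np.ndarray            # Monte-Carlo error of the pooled estimate
    efficiency_loss: np.ndarray
    M: int

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.T))


def rubin_pool(estimates, variances=None, M: Optional[int] = None,
               df_com: Optional[float] = None) -> PooledEstimate:
    """Pool per-imputation estimates by Rubin's rules.

    ``estimates`` is (M, k) (or (M,) for a scalar parameter) point
    estimates; ``variances`` the matching within-imputation variances —
    (M,), (M, k) diagonals, or (M, k, k) full matrices.  Alternatively pass
    a list of :class:`FitResult`, in which case the (dCost, dQALY) pair and
    its joint covariance are pooled.

    ``df_com`` is the complete-data residual dof for the Barnard-Rubin
    small-sample degrees of freedom; omitted, the large-sample limit is
    used.
    """
    if variances is None and len(estimates) and isinstance(estimates[0],
                                                           FitResult):
        variances = np.array([f.delta_cov for f in estimates])
        estimates = np.array([[f.delta_cost, f.delta_qaly]
                              for f in estimates])
    est = np.asarray(estimates, dtype=float)
    if est.ndim == 1:
        est = est[:, None]
    m = M or est.shape[0]
    if m < 2:
        raise ValueError("need at least 2 imputations to pool")
    if est.shape[0] != m:
        raise ValueError("M does not match the number of estimates")
    k = est.shape[1]
    var = np.asarray(variances, dtype=float)
    if var.ndim == 1:
        var = var[:, None]
    if var.ndim == 2:
        if var.shape != (m, k):
            raise ValueError("variances not conformable with estimates")
        Wfull = np.stack([np.diag(v) for v in var])
    elif var.ndim == 3:
        if var.shape != (m, k, k):
            raise ValueError("variances not conformable with estimates")
        Wfull = var
    else:
        raise ValueError("variances must be 1-, 2- or 3-dimensional")

    qbar = est.mean(axis=0)
    W = Wfull.mean(axis=0)
    dev = est - qbar
    B = dev.T @ dev / (m - 1)
    T = W + (1 + 1 / m) * B

    bd = np.diag(B).copy()
    wd = np.maximum(np.diag(W), 1e-300)
    r = (1 + 1 / m) * bd / wd
    lam = (1 + 1 / m) * bd / np.maximum(np.diag(T), 1e-300)
    with np.errstate(divide="ignore"):
        df_old = np.where(lam > 0, (m - 1) / np.maximum(lam, 1e-300) ** 2,
                          np.inf)
    if df_com is not None:
        df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
        df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    else:
        df = df_old
    fmi = (r + 2.0 / (df + 3.0)) / (r + 1.0)
    mce = np.sqrt(bd / m)
    return PooledEstimate(qbar=qbar, W=W, B=B, T=T, df=df, fmi=fmi, mce=mce,
                          efficiency_loss=fmi / m, M=m)


@dataclass
class MiResult:
    """End-to-end multiple-imputation analysis at one horizon."""

    method: str                 # 'milr' | 'mipmm'
    horizon: float
    pooled: PooledEstimate      # over (delta_cost, delta_qaly)
    n_used: int

    @property
    def delta_cost(self) -> float:
        return float(self.pooled.qbar[0])

    @property
    def delta_qaly(self) -> float:
        return float(self.pooled.qbar[1])

    @property
    def delta_cov(self) -> np.ndarray:
        return self.pooled.T


def mi_analysis(data: TrialDataset, cfg: MiceConfig, horizon_years: float,
                rate: float = 0.035, discount_qalys: bool = True,
                include_eq5d0: bool = True) -> MiResult:
    """Impute M times, estimate the bivariate model on each completed set,
    and pool the treatment coefficients by Rubin's rules."""
    completed = mice_impute(data, cfg)
    fits = [estimate_per_dataset(c, horizon_years, rate, discount_qalys,
                                 include_eq5d0) for c in completed]
    df_com = fits[0].n_used - fits[0].coef.shape[0]
    pooled = rubin_pool(fits, df_com=df_com)
    tag = "milr" if cfg.imputer == "linreg" else "mipmm"
    return MiResult(method=tag, horizon=horizon_years, pooled=pooled,
                    n_used=data.n_patients)
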