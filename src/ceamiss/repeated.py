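"""Repeated-measures estimators on the long-format data.

Both estimators fit the same linear model — baseline covariates, a
time factor and a treatment-by-time interaction with baseline as the
reference level — to every observed period cost or EQ-5D measurement:

* RMM: random-intercept linear mixed model (REML by default);
* RMFE: the within (fixed-effects) estimator — least squares on
  subject-demeaned data with a cluster-robust covariance, numerically
  identical to least squares with subject dummies (LSDV).

For the cost model a baseline row with zero cost is added for every subject:
the within transform absorbs the treatment main effect, and only with a
reference time at which the true arm difference is zero do the interaction
coefficients identify absolute per-period incremental costs.

The interaction coefficients are aggregated into incremental totals — a
discounted sum for costs, a discounted trapezium for QALYs — with variances
from the corresponding quadratic form, and a stratified cluster bootstrap
provides paired (dCost, dQALY) draws for the acceptability curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import Schedule, TrialDataset
from .outcomes import _trapezium_weights, discount_factor

__all__ = [
    "RepeatedFit",
    "PointEstimate",
    "fit_rmm",
    "fit_rmfe",
    "incremental_cost_total",
    "incremental_qaly_total",
    "bootstrap_cea",
]


@dataclass
class PointEstimate:
    value: float
    variance: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))

    def ci(self, level: float = 0.95) -> Tuple[float, float]:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        return self.value - z * self.se, self.value + z * self.se


@dataclass
class RepeatedFit:
    """Common shape for RMM/RMFE fits of one outcome."""

    outcome: str               # 'cost' | 'eq5d'
    method: str                # 'rmm' | 'rmfe'
    params: pd.Series          # estimable coefficients
    vcov: pd.DataFrame
    times: List[float]         # non-reference time levels (period end weeks
                               # for cost, EQ-5D weeks for utility)
    delta_names: dict          # time -> interaction coefficient name
    beta1_name: Optional[str]  # treatment main effect (None when absorbed)
    absorbed: List[str]        # regressors absorbed by the within transform
    subject_sd: Optional[float]
    resid_sd: float
    n_obs: int
    n_subjects: int
    loglike: Optional[float] = None
    schedule: Schedule = field(default_factory=Schedule)

    def delta(self) -> pd.Series:
        return pd.Series({t: self.params[self.delta_names[t]]
                          for t in self.times})


# ---------------------------------------------------------------------------
# long-format design construction
# ---------------------------------------------------------------------------

@dataclass
class LongDesign:
    """Stacked observed rows for one outcome, ready for either estimator."""

    y: np.ndarray
    X: pd.DataFrame
    groups: np.ndarray          # integer subject codes, contiguous
    patient_ids: np.ndarray     # code -> patient_id
    arm: np.ndarray             # code -> treatment arm
    times: List[float]          # non-reference time levels (week units)
    delta_names: dict
    invariant_cols: List[str]
    row_slices: List[slice]     # rows per subject code (rows sorted by code)


def build_long_design(data: TrialDataset, outcome: str) -> LongDesign:
    """Assemble y, X from the observed long records of one outcome."""
    base = data.baseline.copy()
    if outcome == "cost":
        obs = data.period_costs[data.period_costs["observed"]].copy()
        end = {t: float(data.schedule.period_end(t))
               for t in range(1, data.schedule.n_periods + 1)}
        obs["time"] = obs["period"].map(end)
        obs = obs.rename(columns={"cost": "y"})[["patient_id", "time", "y"]]
        zero = pd.DataFrame({"patient_id": base["patient_id"],
                             "time": 0.0, "y": 0.0})
        obs = pd.concat([zero, obs], ignore_index=True)
        all_times = [0.0] + sorted(end.values())
    elif outcome == "eq5d":
        obs = data.eq5d[data.eq5d["observed"]].copy()
        obs["time"] = obs["week"].astype(float)
        obs = obs.rename(columns={"utility": "y"})[["patient_id", "time", "y"]]
        all_times = [float(w) for w in data.schedule.eq5d_weeks]
    else:
        raise ValueError("outcome must be 'cost' or 'eq5d'")

    obs = obs.merge(base, on="patient_id", how="left")
    obs = obs.sort_values(["patient_id", "time"], ignore_index=True)

    X = pd.DataFrame({
        "intercept": np.ones(len(obs)),
        "age": obs["age"] - base["age"].mean(),
        "size": obs["size"] - base["size"].mean(),
        "duration": obs["duration"] - base["duration"].mean(),
    })
    site_d = pd.get_dummies(obs["site"], prefix="site", drop_first=True,
                            dtype=float)
    X = pd.concat([X, site_d], axis=1)
    X["treat"] = obs["treat"].astype(float)
    times = [t for t in all_times if t > 0]
    delta_names = {}
    for t in times:
        X[f"time_{t:g}"] = (obs["time"] == t).astype(float)
    for t in times:
        name = f"treat_time_{t:g}"
        X[name] = X["treat"] * X[f"time_{t:g}"]
        delta_names[t] = name

    codes, uniques = pd.factorize(obs["patient_id"], sort=True)
    arm = base.set_index("patient_id").loc[uniques, "treat"].to_numpy()
    boundaries = np.flatnonzero(np.diff(codes, prepend=-1))
    boundaries = np.append(boundaries, len(codes))
    slices = [slice(boundaries[i], boundaries[i + 1])
              for i in range(len(uniques))]
    invariant = ["intercept", "age", "size", "duration", "treat"] \
        + list(site_d.columns)
    return LongDesign(y=obs["y"].to_numpy(dtype=float), X=X, groups=codes,
                      patient_ids=np.asarray(uniques), arm=arm, times=times,
                      delta_names=delta_names, invariant_cols=invariant,
                      row_slices=slices)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _rmm_profile_objective(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                           counts: np.ndarray, reml: bool):
    """Return f(rho) evaluating the profiled (RE)ML criterion at a variance
    ratio rho = subject_var / resid_var, plus the GLS pieces at rho."""
    N, p = X.shape
    ng = len(counts)

    def pieces(rho: float):
        lam = 1.0 - 1.0 / np.sqrt(1.0 + counts * rho)
        gm_y = np.bincount(groups, weights=y, minlength=ng) / counts
        yt = y - lam[groups] * gm_y[groups]
        Xt = np.empty_like(X)
        for j in range(p):
            gm = np.bincount(groups, weights=X[:, j], minlength=ng) / counts
            Xt[:, j] = X[:, j] - lam[groups] * gm[groups]
        G = Xt.T @ Xt
        beta = np.linalg.solve(G, Xt.T @ yt)
        sse = float((yt - Xt @ beta) @ (yt - Xt @ beta))
        logdet_C = float(np.log1p(counts * rho).sum())
        sign, logdet_G = np.linalg.slogdet(G)
        return beta, G, sse, logdet_C, logdet_G

    def objective(rho: float) -> float:
        _, _, sse, logdet_C, logdet_G = pieces(rho)
        if reml:
            return (N - p) * np.log(max(sse, 1e-300)) + logdet_C + logdet_G
        return N * np.log(max(sse, 1e-300)) + logdet_C

    return pieces, objective


def _fit_rmm_design(d: LongDesign, outcome: str, schedule: Schedule,
                    reml: bool = True) -> RepeatedFit:
    """Random-intercept fit by profiled (restricted) maximum likelihood.

    With a single random intercept the marginal covariance per subject is
    ``sigma2 * (I + rho * J)``; GLS for a given rho reduces to partial
    within-subject demeaning, so the criterion is profiled down to a 1-D
    search over log(rho).
    """
    from scipy.optimize import minimize_scalar

    X = d.X.to_numpy(dtype=float)
    y = d.y
    N, p = X.shape
    counts = np.bincount(d.groups).astype(float)
    pieces, objective = _rmm_profile_objective(y, X, d.groups, counts, reml)

    res = minimize_scalar(lambda t: objective(np.exp(t)),
                          bounds=(-15.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError("random-intercept profile optimisation failed: "
                           f"{res.message}; iterations {res.nfev}")
    rho = float(np.exp(res.x))
    if objective(0.0) < res.fun:  # boundary: no subject heterogeneity
        rho = 0.0
    beta, G, sse, logdet_C, logdet_G = pieces(rho)
    dof = (N - p) if reml else N
    sigma2 = sse / dof
    vcov_arr = sigma2 * np.linalg.inv(G)
    loglike = -0.5 * (dof * np.log(2 * np.pi * sigma2) + dof
                      + logdet_C + (logdet_G - p * np.log(sigma2)
                                    if reml else 0.0))
    params = pd.Series(beta, index=d.X.columns)
    vcov = pd.DataFrame(vcov_arr, index=d.X.columns, columns=d.X.columns)
    return RepeatedFit(outcome=outcome, method="rmm", params=params,
                       vcov=vcov, times=d.times, delta_names=d.delta_names,
                       beta1_name="treat", absorbed=[],
                       subject_sd=float(np.sqrt(rho * sigma2)),
                       resid_sd=float(np.sqrt(sigma2)),
                       n_obs=N, n_subjects=len(d.patient_ids),
                       loglike=float(loglike), schedule=schedule)


def _fit_rmfe_design(d: LongDesign, outcome: str,
                     schedule: Schedule) -> RepeatedFit:
    tv_cols = [c for c in d.X.columns if c not in d.invariant_cols]
    Xtv = d.X[tv_cols].to_numpy()
    y = d.y.astype(float)
    # subject demeaning
    ng = d.groups.max() + 1
    cnt = np.bincount(d.groups, minlength=ng).astype(float)
    singletons = (cnt == 1).sum()
    if singletons > 0.5 * ng:
        warnings.warn("majority of subjects have a single observation; "
                      "they contribute nothing to the within estimator",
                      stacklevel=2)
    ymean = np.bincount(d.groups, weights=y, minlength=ng) / cnt
    yd = y - ymean[d.groups]
    Xd = np.empty_like(Xtv)
    for j in range(Xtv.shape[1]):
        m = np.bincount(d.groups, weights=Xtv[:, j], minlength=ng) / cnt
        Xd[:, j] = Xtv[:, j] - m[d.groups]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(yd, Xd).fit(cov_type="cluster",
                                 cov_kwds={"groups": d.groups})
    params = pd.Series(res.params, index=tv_cols)
    vcov = pd.DataFrame(res.cov_params(), index=tv_cols, columns=tv_cols)
    resid_df = max(len(y) - ng - Xtv.shape[1], 1)
    resid_sd = float(np.sqrt(res.ssr / resid_df))
    return RepeatedFit(outcome=outcome, method="rmfe", params=params,
                       vcov=vcov, times=d.times, delta_names=d.delta_names,
                       beta1_name=None, absorbed=list(d.invariant_cols),
                       subject_sd=None, resid_sd=resid_sd,
                       n_obs=len(y), n_subjects=len(d.patient_ids),
                       schedule=schedule)


def fit_rmm(data: TrialDataset, outcome: str, reml: bool = True) -> RepeatedFit:
    """Random-intercept (mixed) fit of the repeated-measures model."""
    d = build_long_design(data, outcome)
    return _fit_rmm_design(d, outcome, data.schedule, reml=reml)


def fit_rmfe(data: TrialDataset, outcome: str) -> RepeatedFit:
    """Within (subject-demeaned) fixed-effects fit; time-invariant regressors
    are absorbed and reported in ``absorbed``."""
    d = build_long_design(data, outcome)
    return _fit_rmfe_design(d, outcome, data.schedule)


# ---------------------------------------------------------------------------
# coefficient aggregation
# ---------------------------------------------------------------------------

def _weight_vector(fit: RepeatedFit, wts: dict,
                   include_beta1: float = 0.0) -> np.ndarray:
    w = pd.Series(0.0, index=fit.params.index)
    for t, v in wts.items():
        w[fit.delta_names[t]] = v
    if fit.beta1_name is not None and include_beta1 != 0.0:
        w[fit.beta1_name] = include_beta1
    return w.to_numpy()


def incremental_cost_total(fit: RepeatedFit, horizon_years: float,
                           rate: float = 0.035) -> PointEstimate:
    """Discounted sum of the per-period interaction coefficients up to the
    horizon, with variance from the corresponding quadratic form."""
    if fit.outcome != "cost":
        raise ValueError("cost fit required")
    sched = fit.schedule
    periods = sched.periods_within(horizon_years)
    if not periods:
        raise ValueError("horizon before the first period boundary")
    wts = {}
    for t in periods:
        wk = float(sched.period_end(t))
        if wk not in fit.delta_names:
            raise ValueError(f"horizon needs period ending week {wk:g}, "
                             "absent from the fit")
        wts[wk] = discount_factor(sched.period_midpoint(t), rate)
    w = _weight_vector(fit, wts)
    val = float(w @ fit.params.to_numpy())
    var = float(w @ fit.vcov.to_numpy() @ w)
    return PointEstimate(val, var)


def incremental_qaly_total(fit: RepeatedFit, horizon_years: float,
                           rate: float = 0.035,
                           discount_qalys: bool = True) -> PointEstimate:
    """Trapezium combination of the arm-difference profile implied by the
    EQ-5D fit: difference at baseline = treatment main effect (0 for the
    within estimator, where it is absorbed and randomisation sets it to
    zero), difference at week w = main effect + interaction at w."""
    if fit.outcome != "eq5d":
        raise ValueError("eq5d fit required")
    hw = Schedule.horizon_week(horizon_years)
    weeks = [0.0] + [t for t in fit.times if t <= hw + 1e-9]
    if not np.isclose(weeks[-1], hw):
        raise ValueError(f"horizon week {hw:g} absent from the fitted grid")
    q_rate = rate if discount_qalys else 0.0
    tw = _trapezium_weights(np.asarray(weeks), q_rate)
    wts = {w: tw[i] for i, w in enumerate(weeks) if w > 0}
    # the baseline weight attaches to beta1; every later weight multiplies
    # (beta1 + delta_w), so beta1 collects the full weight sum
    w = _weight_vector(fit, wts, include_beta1=float(tw.sum()))
    val = float(w @ fit.params.to_numpy())
    var = float(w @ fit.vcov.to_numpy() @ w)
    return PointEstimate(val, var)


# ---------------------------------------------------------------------------
# cluster bootstrap
# ---------------------------------------------------------------------------

def _draw_codes(arm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Subject codes drawn with replacement, stratified by arm."""
    picked = []
    for a in (0, 1):
        pool = np.flatnonzero(arm == a)
        if len(pool):
            picked.append(rng.choice(pool, size=len(pool), replace=True))
    return np.concatenate(picked)


def _resample_design(d: LongDesign, codes_new: np.ndarray) -> LongDesign:
    """Rebuild a design from resampled subject codes; duplicated subjects
    get fresh group codes (cluster bootstrap)."""
    rows = np.concatenate([np.arange(d.row_slices[c].start,
                                     d.row_slices[c].stop)
                           for c in codes_new])
    lens = np.array([d.row_slices[c].stop - d.row_slices[c].start
                     for c in codes_new])
    groups = np.repeat(np.arange(len(codes_new)), lens)
    bnd = np.concatenate([[0], np.cumsum(lens)])
    slices = [slice(bnd[i], bnd[i + 1]) for i in range(len(codes_new))]
    return LongDesign(y=d.y[rows], X=d.X.iloc[rows].reset_index(drop=True),
                      groups=groups, patient_ids=np.arange(len(codes_new)),
                      arm=d.arm[codes_new], times=d.times,
                      delta_names=d.delta_names,
                      invariant_cols=d.invariant_cols, row_slices=slices)


def bootstrap_cea(data: TrialDataset, horizon_years: float, B: int,
                  seed: int, method: str = "rmfe", rate: float = 0.035,
                  discount_qalys: bool = True,
                  max_failure_rate: float = 0.05) -> pd.DataFrame:
    """Paired (delta_cost, delta_qaly) bootstrap draws.

    Patients are resampled with replacement within each arm (stratified,
    clustered by patient); both outcome models are refitted on every
    replicate so the cost-QALY correlation is captured.  Failed replicates
    are redrawn and counted (``.attrs['n_failed']``); more than
    ``max_failure_rate`` failures aborts.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if method not in ("rmm", "rmfe"):
        raise ValueError("method must be 'rmm' or 'rmfe'")
    rng = np.random.default_rng(seed)
    d_cost = build_long_design(data, "cost")
    d_eq = build_long_design(data, "eq5d")
    if not np.array_equal(d_cost.patient_ids, d_eq.patient_ids):
        raise ValueError("cost and EQ-5D designs cover different patients; "
                         "paired resampling needs a common roster")
    fitter = _fit_rmm_design if method == "rmm" else _fit_rmfe_design
    out = np.empty((B, 2))
    n_failed = 0
    b = 0
    while b < B:
        if n_failed > max_failure_rate * B + 5:
            raise RuntimeError(f"bootstrap: {n_failed} failed replicates "
                               f"(> {max_failure_rate:.0%} of B={B})")
        try:
            # one patient resample drives both outcome refits, so the draw
            # pairs capture the cost-QALY correlation
            codes = _draw_codes(d_cost.arm, rng)
            rc = _resample_design(d_cost, codes)
            re_ = _resample_design(d_eq, codes)
            fc = fitter(rc, "cost", data.schedule)
            fe = fitter(re_, "eq5d", data.schedule)
            dc = incremental_cost_total(fc, horizon_years, rate).value
            dq = incremental_qaly_total(fe, horizon_years, rate,
                                        discount_qalys).value
        except Exception:
            n_failed += 1
            continue
        out[b] = (dc, dq)
        b += 1
    draws = pd.DataFrame(out, columns=["delta_cost", "delta_qaly"])
    draws.attrs["n_failed"] = n_failed
    return draws
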