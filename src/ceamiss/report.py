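"""Decision-analytic layer: ICER with dominance handling, parametric and
bootstrap cost-effectiveness acceptability curves, and the six-method
comparison runner.

The CEAC gives, at each willingness-to-pay threshold lambda, the probability
that the net monetary benefit ``lambda*dQ - dC`` is positive.  Parametrically
(bivariate normal estimate) that is
``Phi((lambda*mu_Q - mu_C) / sqrt(lambda^2*s2_Q - 2*lambda*s_CQ + s2_C))``;
from bootstrap or posterior draws it is the fraction of draws with positive
net benefit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .aggregate import BpaConfig, bpa_fit, cca_fit
from .data import TrialDataset
from .diagnostics import pattern_table
from .mice import MiceConfig, mi_analysis
from .outcomes import assemble_aggregate
from .repeated import (bootstrap_cea, fit_rmfe, fit_rmm,
                       incremental_cost_total, incremental_qaly_total)

__all__ = ["icer", "ceac_parametric", "ceac_bootstrap", "CeaSummary",
           "compare_methods", "DEFAULT_LAMBDA_GRID", "ALL_METHODS"]

#: 0 to 50,000 GBP/QALY in 500 steps (covers the usual 20k-30k references)
DEFAULT_LAMBDA_GRID = tuple(range(0, 50_001, 500))

ALL_METHODS = ("rmm", "rmfe", "cca", "mipmm", "milr", "bpa")


def icer(delta_cost: float, delta_qaly: float) -> Union[float, str]:
    """Incremental cost-effectiveness ratio or a dominance label.

    Cheaper and more effective -> ``"dominant"``; dearer and less effective
    -> ``"dominated"``; zero QALY difference -> ``"undefined"``; otherwise
    the ratio dC/dQ in GBP per QALY.
    """
    if delta_qaly == 0:
        return "undefined"
    if delta_cost < 0 and delta_qaly > 0:
        return "dominant"
    if delta_cost > 0 and delta_qaly < 0:
        return "dominated"
    return float(delta_cost / delta_qaly)


def ceac_parametric(delta_cost: float, delta_qaly: float, cov: np.ndarray,
                    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID
                    ) -> pd.DataFrame:
    """CEAC under a bivariate normal (dC, dQ) with covariance ``cov``."""
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("cov must be 2x2")
    if np.any(np.linalg.eigvalsh(cov) < -1e-8 * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance is not positive semi-definite")
    lam = np.asarray(lambda_grid, dtype=float)
    mean_nb = lam * delta_qaly - delta_cost
    var_nb = lam ** 2 * cov[1, 1] - 2 * lam * cov[0, 1] + cov[0, 0]
    var_nb = np.maximum(var_nb, 0.0)
    prob = np.empty_like(lam)
    degenerate = var_nb <= 0
    prob[degenerate] = np.where(mean_nb[degenerate] > 0, 1.0,
                                np.where(mean_nb[degenerate] < 0, 0.0, 0.5))
    ok = ~degenerate
    prob[ok] = norm.cdf(mean_nb[ok] / np.sqrt(var_nb[ok]))
    return pd.DataFrame({"lambda": lam, "probability": prob})


def ceac_bootstrap(draws: pd.DataFrame,
                   lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID
                   ) -> pd.DataFrame:
    """Empirical CEAC: fraction of (dC, dQ) draws with positive net benefit."""
    if len(draws) < 100:
        raise ValueError("need at least 100 draws")
    dc = draws["delta_cost"].to_numpy()
    dq = draws["delta_qaly"].to_numpy()
    lam = np.asarray(lambda_grid, dtype=float)
    nb = lam[:, None] * dq[None, :] - dc[None, :]
    return pd.DataFrame({"lambda": lam,
                         "probability": (nb > 0).mean(axis=1)})


@dataclass
class CeaSummary:
    """One method-by-horizon cell of the comparison."""

    method: str
    horizon: float
    delta_cost: float
    se_cost: float
    ci_cost: Tuple[float, float]
    delta_qaly: float
    se_qaly: float
    ci_qaly: Tuple[float, float]
    cov: np.ndarray
    icer: Union[float, str]
    ceac: pd.DataFrame
    n_used: int
    n_obs: Optional[dict] = None
    error: Optional[str] = None

    def ceac_at(self, lam: float) -> float:
        tbl = self.ceac
        i = int(np.argmin(np.abs(tbl["lambda"].to_numpy() - lam)))
        return float(tbl["probability"].iloc[i])

    def to_row(self) -> dict:
        return {
            "method": self.method, "horizon": self.horizon,
            "n_used": self.n_used,
            "delta_cost": self.delta_cost, "se_cost": self.se_cost,
            "ci_cost_lo": self.ci_cost[0], "ci_cost_hi": self.ci_cost[1],
            "delta_qaly": self.delta_qaly, "se_qaly": self.se_qaly,
            "ci_qaly_lo": self.ci_qaly[0], "ci_qaly_hi": self.ci_qaly[1],
            "icer": self.icer,
            "ceac_30000": self.ceac_at(30_000.0),
            "error": self.error,
        }


def _normal_ci(est: float, se: float) -> Tuple[float, float]:
    return est - 1.959963984540054 * se, est + 1.959963984540054 * se


def _summary_from_normal(method, horizon, dc, dq, cov, n_used, lam_grid,
                         n_obs=None) -> CeaSummary:
    cov = np.asarray(cov, dtype=float)
    se_c, se_q = np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1])
    return CeaSummary(
        method=method, horizon=horizon,
        delta_cost=dc, se_cost=se_c, ci_cost=_normal_ci(dc, se_c),
        delta_qaly=dq, se_qaly=se_q, ci_qaly=_normal_ci(dq, se_q),
        cov=cov, icer=icer(dc, dq),
        ceac=ceac_parametric(dc, dq, cov, lam_grid),
        n_used=n_used, n_obs=n_obs)


def _run_repeated(method, data, horizon, rate, discount_qalys, B, seed,
                  lam_grid) -> CeaSummary:
    fit_c = fit_rmm(data, "cost") if method == "rmm" else fit_rmfe(data, "cost")
    fit_q = fit_rmm(data, "eq5d") if method == "rmm" else fit_rmfe(data, "eq5d")
    dc = incremental_cost_total(fit_c, horizon, rate)
    dq = incremental_qaly_total(fit_q, horizon, rate, discount_qalys)
    draws = bootstrap_cea(data, horizon, B=B, seed=seed, method=method,
                          rate=rate, discount_qalys=discount_qalys)
    cov = np.cov(draws[["delta_cost", "delta_qaly"]].to_numpy().T)
    lo_c, hi_c = np.percentile(draws["delta_cost"], [2.5, 97.5])
    lo_q, hi_q = np.percentile(draws["delta_qaly"], [2.5, 97.5])
    n_obs = {"eq5d": int(data.eq5d["observed"].sum()),
             "cost": int(data.period_costs["observed"].sum())}
    return CeaSummary(
        method=method, horizon=horizon,
        delta_cost=dc.value, se_cost=float(draws["delta_cost"].std(ddof=1)),
        ci_cost=(float(lo_c), float(hi_c)),
        delta_qaly=dq.value, se_qaly=float(draws["delta_qaly"].std(ddof=1)),
        ci_qaly=(float(lo_q), float(hi_q)),
        cov=cov, icer=icer(dc.value, dq.value),
        ceac=ceac_bootstrap(draws, lam_grid),
        n_used=data.n_patients, n_obs=n_obs)


def compare_methods(data: TrialDataset,
                    horizons: Iterable[float] = (1, 3, 5),
                    methods: Iterable[str] = ALL_METHODS,
                    rate: float = 0.035,
                    discount_qalys: bool = True,
                    mice_cfg: Optional[MiceConfig] = None,
                    bpa_cfg: Optional[BpaConfig] = None,
                    B: int = 1000,
                    seed: int = 0,
                    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
                    ) -> dict:
    """Run the requested methods at each horizon with a shared master seed.

    Returns ``{"summaries": list[CeaSummary], "table": DataFrame,
    "ceac": long DataFrame, "patterns": DataFrame}``.  A failing
    method-horizon cell is recorded (``error`` column) and the run
    continues.
    """
    methods = list(methods)
    horizons = list(horizons)
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    ss = np.random.SeedSequence(seed)
    cell_seeds = {}
    children = ss.spawn(len(methods) * len(horizons))
    for i, m in enumerate(methods):
        for j, h in enumerate(horizons):
            cell_seeds[(m, h)] = children[i * len(horizons) + j]

    summaries = []
    patterns = []
    for h in horizons:
        agg = assemble_aggregate(data, h, rate=rate,
                                 discount_qalys=discount_qalys)
        pt = pattern_table(agg)
        pt.insert(0, "horizon", h)
        patterns.append(pt)
        for m in methods:
            seed_m = int(cell_seeds[(m, h)].generate_state(1)[0] % (2 ** 31))
            try:
                if m in ("rmm", "rmfe"):
                    s = _run_repeated(m, data, h, rate, discount_qalys, B,
                                      seed_m, lambda_grid)
                elif m == "cca":
                    fit = cca_fit(agg, data)
                    s = _summary_from_normal(
                        m, h, fit.delta_cost, fit.delta_qaly, fit.delta_cov,
                        fit.n_used, lambda_grid)
                elif m in ("milr", "mipmm"):
                    base = mice_cfg or MiceConfig()
                    cfg = MiceConfig(M=base.M, cycles=base.cycles,
                                     imputer="linreg" if m == "milr" else "pmm",
                                     k_donors=base.k_donors,
                                     predictors=base.predictors, seed=seed_m)
                    res = mi_analysis(data, cfg, h, rate, discount_qalys)
                    s = _summary_from_normal(
                        m, h, res.delta_cost, res.delta_qaly, res.delta_cov,
                        res.n_used, lambda_grid,
                        n_obs={"fmi": list(res.pooled.fmi),
                               "mce": list(res.pooled.mce)})
                elif m == "bpa":
                    base = bpa_cfg or BpaConfig()
                    cfg = BpaConfig(
                        prior_precision=base.prior_precision,
                        aux_prior_precision=base.aux_prior_precision,
                        resid_prior_df=base.resid_prior_df,
                        resid_prior_scale=base.resid_prior_scale,
                        chains=base.chains, iterations=base.iterations,
                        burn_in=base.burn_in, seed=seed_m,
                        rhat_threshold=base.rhat_threshold,
                        include_eq5d0=base.include_eq5d0,
                        include_missingness_model=base.include_missingness_model)
                    res = bpa_fit(agg, data, cfg)
                    s = _summary_from_normal(
                        m, h, res.delta_cost, res.delta_qaly, res.delta_cov,
                        res.n_used, lambda_grid,
                        n_obs={"cost": res.n_obs_cost, "qaly": res.n_obs_qaly})
            except Exception as exc:  # noqa: BLE001 - cell-level isolation
                s = CeaSummary(method=m, horizon=h, delta_cost=np.nan,
                               se_cost=np.nan, ci_cost=(np.nan, np.nan),
                               delta_qaly=np.nan, se_qaly=np.nan,
                               ci_qaly=(np.nan, np.nan),
                               cov=np.full((2, 2), np.nan),
                               icer="error", ceac=pd.DataFrame(
                                   {"lambda": list(lambda_grid),
                                    "probability": np.nan}),
                               n_used=0, error=f"{type(exc).__name__}: {exc}")
            summaries.append(s)

    table = pd.DataFrame([s.to_row() for s in summaries])
    ceac_long = pd.concat(
        [s.ceac.assign(method=s.method, horizon=s.horizon)
         for s in summaries], ignore_index=True)
    return {"summaries": summaries, "table": table, "ceac": ceac_long,
            "patterns": pd.concat(patterns, ignore_index=True)}
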