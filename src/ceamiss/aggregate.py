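"""Aggregate-data estimators of incremental cost and QALY.

``bivariate_fit`` regresses per-patient total cost and total QALY jointly on
baseline covariates.  Because both equations share the same regressors the
seemingly-unrelated-regression estimator collapses to per-equation least
squares; the joint covariance is the Kronecker product of the residual
covariance of (cost, QALY) with the shared inverse Gram matrix, which is what
makes the parametric acceptability curve available.  ``cca_fit`` is the
complete-case version (patients with any missing constituent dropped).

``bpa_fit`` is a Bayesian selection model: total cost and total QALY are
bivariate normal given the covariates, each *missing* total is treated as a
parameter and Gibbs-sampled from its conditional normal given the observed
partner outcome, and logistic submodels of the two missingness indicators
(with follow-up length as an extra predictor) are sampled alongside.  Under
missingness-at-random with distinct priors the outcome inference is
ignorable — the submodels describe the mechanism without feeding back — and
this can be verified by refitting with ``include_missingness_model=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .data import TrialDataset
from .simulate import AGE_CENTER, DURATION_CENTER, SIZE_CENTER

__all__ = ["FitResult", "BpaConfig", "BpaResult", "bivariate_fit", "cca_fit",
           "bpa_fit", "draw_missing_totals", "split_rhat",
           "effective_sample_size"]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _aggregate_design(data: TrialDataset, patient_ids: np.ndarray,
                      include_eq5d0: bool = True,
                      follow_up: bool = False) -> pd.DataFrame:
    base = data.baseline.set_index("patient_id").loc[patient_ids]
    X = pd.DataFrame(index=base.index)
    X["intercept"] = 1.0
    if include_eq5d0:
        eq5d0 = data.eq5d[data.eq5d["week"] == 0] \
            .set_index("patient_id")["utility"]
        X["eq5d0"] = eq5d0.reindex(base.index) - eq5d0.mean()
    X["treat"] = base["treat"].astype(float)
    X["duration"] = base["duration"] - DURATION_CENTER
    X["age"] = base["age"] - AGE_CENTER
    X["size"] = base["size"] - SIZE_CENTER
    for s in sorted(data.baseline["site"].unique())[1:]:
        X[f"site_{s}"] = (base["site"] == s).astype(float)
    if follow_up:
        X["follow_up_years"] = (base["censor_month"]
                                - base["censor_month"].mean()) / 12.0
    return X


def _drop_empty_and_check_rank(X: pd.DataFrame) -> pd.DataFrame:
    """Drop factor-level columns that are identically zero in this subsample;
    raise on genuine collinearity, naming the aliased columns."""
    empty = [c for c in X.columns if c != "intercept"
             and not np.any(X[c].to_numpy())]
    X = X.drop(columns=empty)
    A = X.to_numpy(dtype=float)
    r = np.linalg.matrix_rank(A)
    if r < A.shape[1]:
        # identify aliased columns by pivoted QR
        from scipy.linalg import qr
        _, R, piv = qr(A, mode="economic", pivoting=True)
        keep = piv[:r]
        aliased = [X.columns[j] for j in piv[r:]]
        raise np.linalg.LinAlgError(
            f"singular design; aliased columns: {aliased}")
    return X


# ---------------------------------------------------------------------------
# bivariate normal regression (shared regressors)
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Joint (cost, QALY) regression result in a common shape."""

    method: str
    horizon: float
    coef: pd.DataFrame           # index: design columns; columns: cost, qaly
    vcov: pd.DataFrame           # stacked (cost_*, qaly_*) x same
    resid_cov: np.ndarray        # 2x2 residual covariance of (cost, QALY)
    n_used: int

    @property
    def delta_cost(self) -> float:
        return float(self.coef.loc["treat", "cost"])

    @property
    def delta_qaly(self) -> float:
        return float(self.coef.loc["treat", "qaly"])

    @property
    def delta_cov(self) -> np.ndarray:
        names = ["cost_treat", "qaly_treat"]
        return self.vcov.loc[names, names].to_numpy()


def bivariate_fit(outcomes: pd.DataFrame, data: TrialDataset,
                  drop_incomplete: bool = False,
                  include_eq5d0: bool = True,
                  method_tag: str = "bivariate") -> FitResult:
    """Bivariate normal regression of total cost and total QALY on shared
    baseline regressors.

    With shared regressors the coefficients equal per-equation least
    squares; the joint covariance is ``resid_cov (x) (X'X)^-1``.  The
    treatment coefficients are the incremental cost and QALY.
    """
    rows = outcomes.copy()
    if drop_incomplete:
        rows = rows[rows["cost_complete"] & rows["qaly_complete"]]
    else:
        if rows[["total_cost", "total_qaly"]].isna().any().any():
            raise ValueError("incomplete outcomes passed with "
                             "drop_incomplete=False")
    pids = rows["patient_id"].to_numpy()
    X = _aggregate_design(data, pids, include_eq5d0=include_eq5d0)
    X = _drop_empty_and_check_rank(X)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"only {n} usable patients for {p} regressors")
    A = X.to_numpy(dtype=float)
    Y = rows[["total_cost", "total_qaly"]].to_numpy(dtype=float)
    G = A.T @ A
    Ginv = np.linalg.inv(G)
    B = Ginv @ (A.T @ Y)
    E = Y - A @ B
    S = E.T @ E / (n - p)
    names = [f"{o}_{c}" for o in ("cost", "qaly") for c in X.columns]
    V = np.kron(S, Ginv)
    return FitResult(
        method=method_tag,
        horizon=float(outcomes["horizon"].iloc[0]) if len(outcomes) else np.nan,
        coef=pd.DataFrame(B, index=X.columns, columns=["cost", "qaly"]),
        vcov=pd.DataFrame(V, index=names, columns=names),
        resid_cov=S,
        n_used=n,
    )


def cca_fit(outcomes: pd.DataFrame, data: TrialDataset,
            include_eq5d0: bool = True) -> FitResult:
    """Complete-case analysis: any patient with a missing total is dropped."""
    return bivariate_fit(outcomes, data, drop_incomplete=True,
                         include_eq5d0=include_eq5d0, method_tag="cca")


# ---------------------------------------------------------------------------
# MCMC diagnostics
# ---------------------------------------------------------------------------

def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` has shape (n_chains, n_iter); each chain is split in half,
    and the classic between/within variance ratio is computed on the halves.
    """
    c, n = chains.shape
    half = n // 2
    parts = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n2 = parts.shape
    means = parts.mean(axis=1)
    W = parts.var(axis=1, ddof=1).mean()
    Bv = n2 * means.var(ddof=1)
    var_plus = (n2 - 1) / n2 * W + Bv / n2
    return float(np.sqrt(var_plus / W)) if W > 0 else 1.0


def effective_sample_size(chains: np.ndarray, max_lag: int = 200) -> float:
    """Autocorrelation-based ESS (initial positive sequence estimator),
    summed over chains."""
    c, n = chains.shape
    ess = 0.0
    for ch in chains:
        x = ch - ch.mean()
        v = x.var()
        if v == 0:
            ess += n
            continue
        rho_sum = 0.0
        for lag in range(1, min(max_lag, n - 1)):
            rho = np.dot(x[:-lag], x[lag:]) / ((n - lag) * v)
            if rho < 0.05:
                break
            rho_sum += rho
        ess += n / (1 + 2 * rho_sum)
    return float(ess)


# ---------------------------------------------------------------------------
# Bayesian parametric (selection-model) approach
# ---------------------------------------------------------------------------

@dataclass
class BpaConfig:
    """MCMC settings for the selection model.

    ``prior_precision`` is the normal-prior precision on the regression
    coefficients, applied on an internally standardised outcome scale (costs
    in GBP would otherwise be shrunk drastically by a precision of 0.001);
    the sensitivity range 0.001-0.01 is vague on that scale.
    """

    prior_precision: float = 0.001
    aux_prior_precision: float = 0.01
    resid_prior_df: float = 3.0
    resid_prior_scale: float = 0.01
    chains: int = 2
    iterations: int = 10_000
    burn_in: int = 2_000
    seed: int = 0
    rhat_threshold: float = 1.05
    include_eq5d0: bool = True
    include_missingness_model: bool = True

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.chains < 2:
            raise ValueError("at least 2 chains required for convergence "
                             "diagnostics")
        if not 1e-6 <= self.prior_precision <= 1.0:
            warnings.warn("prior precision outside the usual vague range",
                          stacklevel=2)


@dataclass
class BpaResult:
    """Posterior summaries and draws for the selection model."""

    draws: pd.DataFrame           # columns: chain, delta_cost, delta_qaly
    posterior_mean: np.ndarray    # (delta_cost, delta_qaly)
    posterior_cov: np.ndarray     # 2x2
    rhat: dict
    ess: dict
    aux_accept: dict
    aux_coef_mean: Optional[pd.DataFrame]
    n_used: int
    n_obs_cost: int
    n_obs_qaly: int
    method: str = "bpa"

    @property
    def delta_cost(self) -> float:
        return float(self.posterior_mean[0])

    @property
    def delta_qaly(self) -> float:
        return float(self.posterior_mean[1])

    @property
    def delta_cov(self) -> np.ndarray:
        return self.posterior_cov

    def mcse(self) -> np.ndarray:
        """Monte-Carlo standard error of the two posterior means."""
        out = []
        for k, col in enumerate(["delta_cost", "delta_qaly"]):
            ch = np.array([g[col].to_numpy()
                           for _, g in self.draws.groupby("chain")])
            out.append(self.draws[col].std(ddof=1)
                       / np.sqrt(max(effective_sample_size(ch), 4.0)))
        return np.array(out)


def draw_missing_totals(mu: np.ndarray, Sigma: np.ndarray, Y: np.ndarray,
                        miss_c: np.ndarray, miss_q: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """One Gibbs update of the missing totals given coefficients and Sigma.

    A patient missing one total draws from its conditional normal given the
    observed partner outcome — mean ``mu_1 + s12/s22*(y2 - mu_2)``, variance
    ``s11 - s12^2/s22`` — and a patient missing both draws from the joint
    bivariate normal.  ``Y`` is modified in place and returned.
    """
    s11, s22 = Sigma[0, 0], Sigma[1, 1]
    s12 = Sigma[0, 1]
    both = miss_c & miss_q
    only_c = miss_c & ~miss_q
    only_q = miss_q & ~miss_c
    if both.any():
        L = np.linalg.cholesky(Sigma)
        Y[both] = mu[both] + rng.standard_normal((both.sum(), 2)) @ L.T
    if only_c.any():
        cond_m = mu[only_c, 0] + s12 / s22 * (Y[only_c, 1] - mu[only_c, 1])
        cond_v = s11 - s12 ** 2 / s22
        Y[only_c, 0] = cond_m + rng.standard_normal(only_c.sum()) \
            * np.sqrt(max(cond_v, 1e-12))
    if only_q.any():
        cond_m = mu[only_q, 1] + s12 / s11 * (Y[only_q, 0] - mu[only_q, 0])
        cond_v = s22 - s12 ** 2 / s11
        Y[only_q, 1] = cond_m + rng.standard_normal(only_q.sum()) \
            * np.sqrt(max(cond_v, 1e-12))
    return Y


def _gibbs_chain(A, Y_std, miss_c, miss_q, Z, cfg: BpaConfig,
                 rng: np.random.Generator, n_keep: int, treat_row: int):
    """One chain of the Gibbs sampler on the standardised scale."""
    n, p = A.shape
    G = A.T @ A
    tau = cfg.prior_precision
    Y = Y_std.copy()
    # initialise missing cells at the observed-arm means (0 after
    # standardisation)
    Y[miss_c, 0] = 0.0
    Y[miss_q, 1] = 0.0
    Sigma = np.eye(2)
    Bmat = np.zeros((p, 2))
    out = np.empty((n_keep, 2))
    S0 = cfg.resid_prior_scale * np.eye(2)

    # auxiliary logistic models (sampled alongside; no feedback under MAR)
    use_aux = cfg.include_missingness_model
    if use_aux:
        q = Z.shape[1]
        alpha = np.zeros((2, q))
        m_ind = np.column_stack([miss_c.astype(float), miss_q.astype(float)])
        step = np.full(2, 0.05)
        acc = np.zeros(2)
        tries = np.zeros(2)

        def aux_logpost(a, m):
            lp = Z @ a
            return (m * lp - np.logaddexp(0, lp)).sum() \
                - 0.5 * cfg.aux_prior_precision * a @ a

    total_iter = cfg.iterations
    burn = cfg.burn_in
    kept = 0
    for it in range(total_iter):
        # --- missing totals | B, Sigma ---
        mu = A @ Bmat
        Y = draw_missing_totals(mu, Sigma, Y, miss_c, miss_q, rng)

        # --- coefficients | Y, Sigma ---
        Om = np.linalg.inv(Sigma)
        P = np.kron(Om, G) + tau * np.eye(2 * p)
        XtY = A.T @ Y          # p x 2
        rhs = np.concatenate([Om[0, 0] * XtY[:, 0] + Om[0, 1] * XtY[:, 1],
                              Om[1, 0] * XtY[:, 0] + Om[1, 1] * XtY[:, 1]])
        Lp = np.linalg.cholesky(P)
        mean_b = np.linalg.solve(P, rhs)
        z = rng.standard_normal(2 * p)
        b = mean_b + np.linalg.solve(Lp.T, z)
        Bmat = np.column_stack([b[:p], b[p:]])

        # --- residual covariance | Y, B ---
        E = Y - A @ Bmat
        Sigma = invwishart.rvs(df=cfg.resid_prior_df + n,
                               scale=S0 + E.T @ E, random_state=rng)

        # --- auxiliary logistic submodels (random-walk Metropolis) ---
        if use_aux:
            for j in range(2):
                prop = alpha[j] + step[j] * rng.standard_normal(q)
                lp_new = aux_logpost(prop, m_ind[:, j])
                lp_old = aux_logpost(alpha[j], m_ind[:, j])
                tries[j] += 1
                if np.log(rng.random()) < lp_new - lp_old:
                    alpha[j] = prop
                    acc[j] += 1
                if it < burn and it % 50 == 49:
                    rate = acc[j] / max(tries[j], 1)
                    step[j] *= np.exp(np.clip(rate - 0.25, -0.5, 0.5))

        if it >= burn:
            out[kept] = Bmat[treat_row]
            kept += 1

    aux_info = None
    if use_aux:
        aux_info = (alpha, acc / np.maximum(tries, 1))
    return out, aux_info


def bpa_fit(outcomes: pd.DataFrame, data: TrialDataset,
            cfg: Optional[BpaConfig] = None) -> BpaResult:
    """Selection-model MCMC on aggregate totals with missing totals as
    parameters.  All patients enter; any subset of totals may be missing."""
    cfg = cfg or BpaConfig()
    pids = outcomes["patient_id"].to_numpy()
    X = _aggregate_design(data, pids, include_eq5d0=cfg.include_eq5d0)
    X = _drop_empty_and_check_rank(X)
    A = X.to_numpy(dtype=float)
    Z = _aggregate_design(data, pids, include_eq5d0=cfg.include_eq5d0,
                          follow_up=True)
    Z = Z.loc[:, [c for c in Z.columns]]  # aux design keeps follow-up length
    Zm = Z.to_numpy(dtype=float)

    Yc = outcomes["total_cost"].to_numpy(dtype=float)
    Yq = outcomes["total_qaly"].to_numpy(dtype=float)
    miss_c = np.isnan(Yc)
    miss_q = np.isnan(Yq)
    # standardise on observed cells
    mC, sC = np.nanmean(Yc), max(np.nanstd(Yc, ddof=1), 1e-9)
    mQ, sQ = np.nanmean(Yq), max(np.nanstd(Yq, ddof=1), 1e-9)
    Ys = np.column_stack([(Yc - mC) / sC, (Yq - mQ) / sQ])

    treat_row = list(X.columns).index("treat")
    n_keep = cfg.iterations - cfg.burn_in
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    chains = []
    aux_coefs = []
    aux_acc = []
    for c in range(cfg.chains):
        rng = np.random.default_rng(seeds[c])
        draws, aux = _gibbs_chain(A, Ys, miss_c, miss_q, Zm, cfg, rng,
                                  n_keep, treat_row)
        chains.append(draws)
        if aux is not None:
            aux_coefs.append(aux[0])
            aux_acc.append(aux[1])

    # back to original scales
    scale = np.array([sC, sQ])
    all_draws = []
    for c, dr in enumerate(chains):
        df = pd.DataFrame(dr * scale, columns=["delta_cost", "delta_qaly"])
        df.insert(0, "chain", c)
        all_draws.append(df)
    draws = pd.concat(all_draws, ignore_index=True)

    rhat = {}
    ess = {}
    for col in ("delta_cost", "delta_qaly"):
        ch = np.array([g[col].to_numpy() for _, g in draws.groupby("chain")])
        rhat[col] = split_rhat(ch)
        ess[col] = effective_sample_size(ch)
    worst = max(rhat.values())
    if worst > cfg.rhat_threshold:
        summ = draws.groupby("chain")[["delta_cost", "delta_qaly"]] \
            .agg(["mean", "std"])
        raise RuntimeError(
            f"MCMC not converged: max split-Rhat {worst:.3f} > "
            f"{cfg.rhat_threshold}\nper-chain trace summary:\n{summ}")

    post = draws[["delta_cost", "delta_qaly"]].to_numpy()
    aux_mean = None
    if aux_coefs:
        aux_mean = pd.DataFrame(np.mean(aux_coefs, axis=0),
                                index=["cost_missing", "qaly_missing"],
                                columns=Z.columns)
    return BpaResult(
        draws=draws,
        posterior_mean=post.mean(axis=0),
        posterior_cov=np.cov(post.T),
        rhat=rhat,
        ess=ess,
        aux_accept={"cost": float(np.mean([a[0] for a in aux_acc]))
                    if aux_acc else np.nan,
                    "qaly": float(np.mean([a[1] for a in aux_acc]))
                    if aux_acc else np.nan},
        aux_coef_mean=aux_mean,
        n_used=len(pids),
        n_obs_cost=int((~miss_c).sum()),
        n_obs_qaly=int((~miss_q).sum()),
    )
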