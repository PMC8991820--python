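"""Synthetic staggered-recruitment trial generator.

Emulates the design of a two-arm venous-ulcer trial in which 450 patients
were recruited over ~3 years with a fixed calendar study end, giving each
patient between ~2.5 and ~5.5 years of administratively censored follow-up.
Costs are recorded in 12 roughly-monthly periods over year 1 and yearly
thereafter; EQ-5D utility is recorded at weeks 0/6/26/52 plus exactly one
late "telephone" follow-up whose week depends on the recruitment date (the
latest post-year-1 grid week the patient reaches before the study closes).

Outcomes are generated from a linear model with a period/week factor, a
treatment-by-time interaction (the true incremental effect profile), baseline
covariate effects, a shared per-patient intercept and independent residuals.
Item missingness is then imposed in two layers: structural (censoring and the
telephone rule — deterministic given the recruitment date) and stochastic MAR
(a logistic model on baseline covariates, follow-up week and, optionally, the
most recent observed utility).

The pre-missingness truth is retained in shadow tables so estimator recovery
can be scored; estimators never see them.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .data import WEEKS_PER_MONTH, WEEKS_PER_YEAR, Schedule, TrialDataset

logger = logging.getLogger(__name__)

__all__ = [
    "MissingnessModel",
    "CovariateEffects",
    "TrialConfig",
    "generate_complete",
    "impose_missingness",
    "make_trial",
    "true_incremental_cost",
    "true_incremental_qaly",
]

# centring constants for covariates on the generating side (years, cm2, years)
AGE_CENTER = 67.0
SIZE_CENTER = 6.0
DURATION_CENTER = 1.6

UTILITY_FLOOR = -0.594
N_SITES = 6
SITE_PROBS = (0.28, 0.22, 0.17, 0.13, 0.12, 0.08)


def _zeros_site() -> tuple:
    return (0.0,) * N_SITES


@dataclass(frozen=True)
class MissingnessModel:
    """Logistic (MAR) item-missingness mechanism.

    ``logit(p_miss) = intercept + treat*TREAT + duration*DURATION_c
    + age*AGE_c + size*SIZE_c + site[SITE] + week[w]
    + (prev_utility + treat_prev_utility*TREAT) * last observed utility``.

    Covariates enter centred (same constants as the outcome model).  The
    ``week`` mapping plays the role of a follow-up-time factor; weeks absent
    from it contribute 0.  ``intercept=-inf`` disables the mechanism.
    """

    intercept: float = -np.inf
    treat: float = 0.0
    duration: float = 0.0
    age: float = 0.0
    size: float = 0.0
    site: tuple = field(default_factory=_zeros_site)
    week: Mapping[float, float] = field(default_factory=dict)
    prev_utility: float = 0.0
    treat_prev_utility: float = 0.0

    def base_logit(self, baseline: pd.DataFrame) -> np.ndarray:
        """Patient-level part of the logit (everything except week/history)."""
        lp = np.full(len(baseline), self.intercept, dtype=float)
        lp += self.treat * baseline["treat"].to_numpy()
        lp += self.duration * (baseline["duration"].to_numpy() - DURATION_CENTER)
        lp += self.age * (baseline["age"].to_numpy() - AGE_CENTER)
        lp += self.size * (baseline["size"].to_numpy() - SIZE_CENTER)
        lp += np.asarray(self.site)[baseline["site"].to_numpy()]
        return lp


def _default_eq5d_missing() -> MissingnessModel:
    return MissingnessModel(
        intercept=-2.2,
        age=0.015,
        site=(0.0, 0.2, -0.2, 0.1, -0.1, 0.0),
        week={6: 0.0, 26: 0.2, 52: 0.4, 104: 0.8, 156: 0.9, 208: 1.0, 260: 1.1},
    )


def _default_cost_missing() -> MissingnessModel:
    # cost items are largely recoverable from case notes, so item-level cost
    # missingness is an order of magnitude rarer than for the questionnaire
    return MissingnessModel(
        intercept=-5.2,
        age=0.01,
        week={52: 0.2, 104: 0.5, 156: 0.6, 208: 0.7, 260: 0.8},
    )


@dataclass(frozen=True)
class CovariateEffects:
    """Common (time-constant) baseline covariate effects on both outcomes.

    ``cost`` coefficients are GBP per period per centred unit; ``eq5d`` are
    utility-index points per centred unit.  ``*_site`` are per-site offsets.
    """

    cost: Mapping[str, float] = field(default_factory=lambda: {
        "age": 1.0, "size": 2.5, "duration": 4.0})
    cost_site: tuple = (0.0, 20.0, -20.0, 10.0, -10.0, 0.0)
    eq5d: Mapping[str, float] = field(default_factory=lambda: {
        "age": -0.002, "size": -0.003, "duration": -0.004})
    eq5d_site: tuple = (0.0, 0.02, -0.02, 0.01, -0.01, 0.0)


# constant true utility effect chosen so the undiscounted incremental QALY
# over 3 years equals 0.07 (trapezium over weeks 0,6,26,52,104,156)
DEFAULT_UTILITY_EFFECT = 0.07 * 52.0 / 153.0


def _default_eq5d_effects() -> Dict[float, float]:
    return {w: DEFAULT_UTILITY_EFFECT for w in (6, 26, 52, 104, 156, 208, 260)}


def _default_period_means() -> tuple:
    # declining monthly costs over year 1, then yearly aggregates
    return (260, 230, 210, 190, 175, 160, 150, 140, 135, 130, 125, 120,
            520, 480, 450, 430)


def _default_week_means() -> Dict[float, float]:
    return {0: 0.60, 6: 0.64, 26: 0.69, 52: 0.71, 104: 0.71, 156: 0.70,
            208: 0.70, 260: 0.69}


@dataclass
class TrialConfig:
    """Generating parameters; the defaults are the emulated study conditions."""

    n_patients: int = 450
    recruit_window_months: float = 36.0
    study_end_month: float = 65.0
    arm_allocation: float = 0.5
    #: true per-period incremental cost of the early arm (GBP), periods 1..16
    cost_effects: Sequence[float] = field(default_factory=lambda: np.zeros(16))
    #: true incremental utility at each post-baseline EQ-5D week
    eq5d_effects: Mapping[float, float] = field(default_factory=_default_eq5d_effects)
    #: true baseline (week-0) arm difference in utility; 0 under randomisation
    eq5d_baseline_effect: float = 0.0
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    #: mean cost per period (GBP) and mean utility per week in the control arm
    period_means: Sequence[float] = field(default_factory=_default_period_means)
    week_means: Mapping[float, float] = field(default_factory=_default_week_means)
    subject_sd_cost: float = 40.0
    subject_sd_eq5d: float = 0.10
    resid_sd_cost: float = 60.0
    resid_sd_eq5d: float = 0.07
    missing_cost: MissingnessModel = field(default_factory=_default_cost_missing)
    missing_eq5d: MissingnessModel = field(default_factory=_default_eq5d_missing)
    death_rate: float = 0.0  # annual hazard
    discount_rate: float = 0.035  # annual
    schedule: Schedule = field(default_factory=Schedule)
    seed: int = 20230101

    def __post_init__(self):
        self.cost_effects = np.asarray(self.cost_effects, dtype=float)
        if len(self.cost_effects) != self.schedule.n_periods:
            raise ValueError(
                f"cost_effects must have {self.schedule.n_periods} entries, "
                f"got {len(self.cost_effects)}")
        post_weeks = set(w for w in self.schedule.eq5d_weeks if w > 0)
        if set(self.eq5d_effects) != post_weeks:
            raise ValueError("eq5d_effects must be indexed by the post-baseline "
                             f"EQ-5D week grid {sorted(post_weeks)}")
        if len(self.period_means) != self.schedule.n_periods:
            raise ValueError("period_means length mismatch with schedule")
        for name in ("subject_sd_cost", "subject_sd_eq5d",
                     "resid_sd_cost", "resid_sd_eq5d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.arm_allocation <= 1:
            raise ValueError("arm_allocation must be in [0, 1]")
        if self.death_rate < 0 or self.discount_rate < 0:
            raise ValueError("rates must be >= 0")

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["cost_effects"] = [float(x) for x in self.cost_effects]
        d["eq5d_effects"] = {float(k): float(v) for k, v in self.eq5d_effects.items()}
        d["week_means"] = {float(k): float(v) for k, v in self.week_means.items()}
        d["period_means"] = [float(x) for x in self.period_means]
        d["schedule"] = {"period_boundaries": list(self.schedule.period_boundaries),
                         "eq5d_weeks": list(self.schedule.eq5d_weeks)}
        for key in ("missing_cost", "missing_eq5d"):
            d[key]["week"] = {float(k): float(v) for k, v in d[key]["week"].items()}
            d[key]["site"] = list(d[key]["site"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrialConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["schedule"] = Schedule(
            period_boundaries=tuple(d["schedule"]["period_boundaries"]),
            eq5d_weeks=tuple(d["schedule"]["eq5d_weeks"]))
        d["covariate_effects"] = CovariateEffects(
            cost=d["covariate_effects"]["cost"],
            cost_site=tuple(d["covariate_effects"]["cost_site"]),
            eq5d=d["covariate_effects"]["eq5d"],
            eq5d_site=tuple(d["covariate_effects"]["eq5d_site"]))
        for key in ("missing_cost", "missing_eq5d"):
            d[key]["site"] = tuple(d[key]["site"])
            d[key] = MissingnessModel(**d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_complete(config: TrialConfig) -> TrialDataset:
    """Generate a fully observed trial (the truth, including post-censoring
    values; censoring is applied later by :func:`impose_missingness`)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    sched = config.schedule

    baseline = pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "treat": rng.binomial(1, config.arm_allocation, n),
        "age": np.clip(rng.normal(AGE_CENTER, 12.0, n), 25, 95).round(1),
        "size": np.round(np.exp(rng.normal(np.log(SIZE_CENTER) - 0.32, 0.8, n)), 2),
        "duration": np.round(np.exp(rng.normal(np.log(DURATION_CENTER) - 0.5, 1.0, n)), 2),
        "site": rng.choice(N_SITES, n, p=SITE_PROBS),
        "ethnicity": rng.binomial(1, 0.85, n),
        "diabetes": rng.binomial(1, 0.12, n),
        "dvt_history": rng.binomial(1, 0.10, n),
        "trial_leg": rng.binomial(1, 0.5, n),
    })
    baseline["recruit_month"] = np.round(
        rng.uniform(0, config.recruit_window_months, n), 2)
    baseline["censor_month"] = config.study_end_month - baseline["recruit_month"]

    if config.death_rate > 0:
        death_years = rng.exponential(1.0 / config.death_rate, n)
        death_month = death_years * 12.0
        baseline["death_month"] = np.where(
            death_month < baseline["censor_month"], np.round(death_month, 2), np.nan)
    else:
        baseline["death_month"] = np.nan

    eff = config.covariate_effects
    age_c = baseline["age"].to_numpy() - AGE_CENTER
    size_c = baseline["size"].to_numpy() - SIZE_CENTER
    dur_c = baseline["duration"].to_numpy() - DURATION_CENTER
    site = baseline["site"].to_numpy()
    treat = baseline["treat"].to_numpy()

    cov_cost = (eff.cost.get("age", 0) * age_c + eff.cost.get("size", 0) * size_c
                + eff.cost.get("duration", 0) * dur_c + np.asarray(eff.cost_site)[site])
    cov_u = (eff.eq5d.get("age", 0) * age_c + eff.eq5d.get("size", 0) * size_c
             + eff.eq5d.get("duration", 0) * dur_c + np.asarray(eff.eq5d_site)[site])

    subj_cost = rng.normal(0, config.subject_sd_cost, n)
    subj_u = rng.normal(0, config.subject_sd_eq5d, n)

    death_week = baseline["death_month"].to_numpy() * WEEKS_PER_MONTH  # NaN-safe

    # period costs
    rows = []
    for t in range(1, sched.n_periods + 1):
        mu = (config.period_means[t - 1] + config.cost_effects[t - 1] * treat
              + cov_cost + subj_cost)
        y = mu + rng.normal(0, config.resid_sd_cost, n)
        y = np.maximum(y, 0.0)
        start_w, _ = sched.period_interval(t)
        dead = ~np.isnan(death_week) & (death_week <= start_w)
        y[dead] = 0.0
        rows.append(pd.DataFrame({
            "patient_id": baseline["patient_id"], "period": t,
            "cost": np.round(y, 2)}))
    period_costs = pd.concat(rows, ignore_index=True)
    floored = (period_costs["cost"] == 0).mean()
    if floored > 0.05:
        logger.info("cost floor at 0 applied to %.1f%% of period costs",
                    100 * floored)

    # EQ-5D utilities
    rows = []
    for w in sched.eq5d_weeks:
        mu = (config.week_means[w] + config.eq5d_baseline_effect * treat
              + (config.eq5d_effects[w] if w > 0 else 0.0) * treat
              + cov_u + subj_u)
        u = mu + rng.normal(0, config.resid_sd_eq5d, n)
        u = np.clip(u, UTILITY_FLOOR, 1.0)
        dead = ~np.isnan(death_week) & (death_week <= w)
        u[dead] = 0.0
        rows.append(pd.DataFrame({
            "patient_id": baseline["patient_id"], "week": w,
            "utility": np.round(u, 4)}))
    eq5d = pd.concat(rows, ignore_index=True)

    period_costs["observed"] = True
    period_costs["scheduled"] = True
    eq5d["observed"] = True
    eq5d["scheduled"] = True

    period_costs = period_costs.sort_values(["patient_id", "period"], ignore_index=True)
    eq5d = eq5d.sort_values(["patient_id", "week"], ignore_index=True)
    ds = TrialDataset(baseline=baseline, period_costs=period_costs, eq5d=eq5d,
                      schedule=sched)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# missingness imposition
# ---------------------------------------------------------------------------

def impose_missingness(data: TrialDataset, config: TrialConfig,
                       telephone: bool = True) -> TrialDataset:
    """Apply the two missingness layers to a complete dataset.

    Layer (a) — structural, deterministic given the recruitment date: cost
    periods ending after the censoring week become missing-by-design
    (``scheduled=False``), EQ-5D weeks after censoring likewise, and of the
    post-year-1 EQ-5D weeks within follow-up only the latest ("telephone")
    is kept.  Set ``telephone=False`` to disable the telephone pruning (the
    degenerate everything-in-window configuration used for pass-through
    checks).

    Layer (b) — stochastic MAR: each still-scheduled item goes missing with
    probability ``expit`` of the configured logit.  Week-0 EQ-5D (the
    baseline covariate) is never stochastically missing.  Items already
    zeroed by death remain observed ("assigned zero costs and HRQOL
    thereafter").

    The complete values are kept in the shadow tables of the returned
    dataset.  The operation draws from a generator seeded by
    ``config.seed + 1`` so it is reproducible and independent of generation.
    """
    out = data.copy()
    out.shadow_costs = data.period_costs[["patient_id", "period", "cost"]].copy()
    out.shadow_eq5d = data.eq5d[["patient_id", "week", "utility"]].copy()
    rng = np.random.default_rng(np.uint32(config.seed) + 1)

    base = out.baseline.set_index("patient_id")
    censor_week = (base["censor_month"] * WEEKS_PER_MONTH)
    death_week = (base["death_month"] * WEEKS_PER_MONTH)

    pc = out.period_costs
    end_week = pc["period"].map({t: out.schedule.period_end(t)
                                 for t in range(1, out.schedule.n_periods + 1)})
    cw_pc = pc["patient_id"].map(censor_week)
    structural_pc = end_week.to_numpy() > cw_pc.to_numpy() + 1e-9

    eq = out.eq5d
    cw_eq = eq["patient_id"].map(censor_week).to_numpy()
    week = eq["week"].to_numpy()
    structural_eq = week > cw_eq + 1e-9
    if telephone:
        tel = censor_week.apply(out.schedule.telephone_week)
        tel_eq = eq["patient_id"].map(tel).to_numpy()
        late = week > 52
        structural_eq |= late & (week != tel_eq)

    # death overrides: post-death items are zero and stay observed
    dw_pc = pc["patient_id"].map(death_week).to_numpy()
    start_week = end_week.to_numpy() - np.diff(
        np.asarray(out.schedule.period_boundaries))[pc["period"].to_numpy() - 1]
    dead_pc = ~np.isnan(dw_pc) & (dw_pc <= start_week)
    dw_eq = eq["patient_id"].map(death_week).to_numpy()
    dead_eq = ~np.isnan(dw_eq) & (dw_eq <= week)

    structural_pc &= ~dead_pc
    structural_eq &= ~dead_eq

    # layer (b): stochastic MAR on still-scheduled items
    base_lp_cost = pd.Series(config.missing_cost.base_logit(out.baseline).astype(float),
                             index=out.baseline["patient_id"])
    lp_pc = pc["patient_id"].map(base_lp_cost).to_numpy()
    wk_eff = np.array([config.missing_cost.week.get(w, 0.0) for w in end_week])
    lp_pc = lp_pc + wk_eff
    with np.errstate(invalid="ignore"):
        stoch_pc = (rng.random(len(pc)) < expit(lp_pc)) & ~structural_pc & ~dead_pc

    # EQ-5D: sequential over weeks so the mechanism can use the most recent
    # observed utility (outcome-history-dependent MAR)
    mm = config.missing_eq5d
    base_lp_eq = mm.base_logit(out.baseline).astype(float)
    hist_coef = (mm.prev_utility
                 + mm.treat_prev_utility * out.baseline["treat"].to_numpy())
    use_history = mm.prev_utility != 0.0 or mm.treat_prev_utility != 0.0
    pid_order = out.baseline["patient_id"].to_numpy()
    eq_wide_u = eq.pivot(index="patient_id", columns="week", values="utility") \
                  .reindex(pid_order)
    struct_wide = pd.DataFrame(
        structural_eq, index=eq.index).assign(
        patient_id=eq["patient_id"], week=eq["week"]).pivot(
        index="patient_id", columns="week", values=0).reindex(pid_order)
    stoch_wide = pd.DataFrame(False, index=eq_wide_u.index,
                              columns=eq_wide_u.columns)
    dead_wide = pd.DataFrame(
        dead_eq, index=eq.index).assign(
        patient_id=eq["patient_id"], week=eq["week"]).pivot(
        index="patient_id", columns="week", values=0).reindex(pid_order)
    last_obs_u = eq_wide_u[0].to_numpy().copy()  # week-0 never missing
    for w in out.schedule.eq5d_weeks:
        if w == 0:
            continue
        lp = base_lp_eq + mm.week.get(w, 0.0)
        if use_history:
            lp = lp + hist_coef * last_obs_u
        draw = rng.random(len(lp)) < expit(lp)
        eligible = (~struct_wide[w].to_numpy()) & (~dead_wide[w].to_numpy())
        miss_w = draw & eligible
        stoch_wide[w] = miss_w
        seen = eligible & ~miss_w
        last_obs_u[seen] = eq_wide_u[w].to_numpy()[seen]

    stoch_eq = stoch_wide.stack().reindex(
        pd.MultiIndex.from_frame(eq[["patient_id", "week"]])).to_numpy()

    pc.loc[structural_pc, "scheduled"] = False
    pc["observed"] = ~(structural_pc | stoch_pc)
    pc.loc[~pc["observed"], "cost"] = np.nan
    eq.loc[structural_eq, "scheduled"] = False
    eq["observed"] = ~(structural_eq | stoch_eq.astype(bool))
    eq.loc[~eq["observed"], "utility"] = np.nan

    out.validate()
    return out


def make_trial(config: TrialConfig, telephone: bool = True) -> TrialDataset:
    """Convenience: generate a complete trial and impose missingness."""
    return impose_missingness(generate_complete(config), config,
                              telephone=telephone)


# ---------------------------------------------------------------------------
# closed-form truth (for recovery scoring)
# ---------------------------------------------------------------------------

def true_incremental_cost(config: TrialConfig, horizon_years: float,
                          rate: Optional[float] = None) -> float:
    """Discounted sum of the true per-period cost effects up to the horizon."""
    from .outcomes import discount_factor
    rate = config.discount_rate if rate is None else rate
    sched = config.schedule
    return float(sum(
        config.cost_effects[t - 1] * discount_factor(sched.period_midpoint(t), rate)
        for t in sched.periods_within(horizon_years)))


def true_incremental_qaly(config: TrialConfig, horizon_years: float,
                          rate: Optional[float] = None) -> float:
    """Discounted trapezium of the true incremental-utility profile."""
    from .outcomes import discount_factor
    rate = config.discount_rate if rate is None else rate
    weeks = config.schedule.eq5d_weeks_within(horizon_years)
    d = {w: (config.eq5d_baseline_effect
             + (config.eq5d_effects[w] if w > 0 else 0.0)) for w in weeks}
    total = 0.0
    for a, b in zip(weeks[:-1], weeks[1:]):
        mid = 0.5 * (a + b)
        total += (0.5 * (d[a] + d[b]) * (b - a) / WEEKS_PER_YEAR
                  * discount_factor(mid, rate))
    return float(total)
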