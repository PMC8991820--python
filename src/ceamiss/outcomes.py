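"""Deterministic outcome transforms shared by every estimator.

Per-patient discounted total cost, trapezium-rule ("area under the curve")
QALYs, and assembly of the aggregate-format analysis table at a time horizon.
Discounting assigns each cost period / utility segment to the completed year
at its midpoint, so everything inside year 1 is undiscounted.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .data import WEEKS_PER_MONTH, WEEKS_PER_YEAR, Schedule, TrialDataset

__all__ = [
    "discount_factor",
    "total_cost",
    "qaly_trapezium",
    "assemble_aggregate",
]


def discount_factor(week: float, rate: float) -> float:
    """``1/(1+rate)**y`` with ``y`` the completed years elapsed at ``week``.

    ``week`` is usually an interval midpoint.  Year-1 items (week < 52) are
    undiscounted.
    """
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    y = int(np.floor(week / WEEKS_PER_YEAR))
    return 1.0 / (1.0 + rate) ** y


def total_cost(costs: Mapping[int, float], horizon_years: float, rate: float,
               schedule: Optional[Schedule] = None) -> float:
    """Discounted sum of period costs up to the horizon; NaN if any needed
    period is missing (NaN) or absent from ``costs``."""
    schedule = schedule or Schedule()
    total = 0.0
    for t in schedule.periods_within(horizon_years):
        c = costs.get(t, np.nan)
        if c is None or np.isnan(c):
            return np.nan
        total += c * discount_factor(schedule.period_midpoint(t), rate)
    return total


def _trapezium_weights(weeks: np.ndarray, rate: float) -> np.ndarray:
    """Per-grid-point weights such that QALY = sum(w_i * u_i)."""
    w = np.zeros(len(weeks))
    for j in range(len(weeks) - 1):
        a, b = weeks[j], weeks[j + 1]
        seg = 0.5 * (b - a) / WEEKS_PER_YEAR * discount_factor(0.5 * (a + b), rate)
        w[j] += seg
        w[j + 1] += seg
    return w


def qaly_trapezium(utilities: Mapping[float, float], horizon_years: float,
                   rate: float = 0.0) -> float:
    """Discounted trapezium-rule QALY over the supplied week grid.

    The grid must reach the horizon: either the horizon week is a grid point,
    or a segment straddles it, in which case the segment is truncated at the
    boundary with the utility linearly interpolated between its endpoints.
    Returns NaN if any needed utility is missing.

    Raises ``ValueError`` when the grid stops short of the horizon (the
    horizon point is absent and nothing lies beyond it).
    """
    hw = Schedule.horizon_week(horizon_years)
    weeks = np.array(sorted(utilities))
    if len(weeks) == 0 or weeks.max() < hw - 1e-9:
        raise ValueError(f"utility grid does not reach horizon week {hw:g}")
    vals = {w: utilities[w] for w in weeks}
    if not np.any(np.isclose(weeks, hw)):
        # truncate the straddling segment at the horizon boundary
        below = weeks[weeks < hw]
        above = weeks[weeks > hw]
        a, b = below[-1], above[0]
        ua, ub = vals[a], vals[b]
        if np.isnan(ua) or np.isnan(ub):
            return np.nan
        vals[hw] = ua + (ub - ua) * (hw - a) / (b - a)
        weeks = np.append(below, hw)
    else:
        weeks = weeks[weeks <= hw + 1e-9]
    u = np.array([vals[w] for w in weeks], dtype=float)
    if np.isnan(u).any():
        return np.nan
    return float(_trapezium_weights(weeks, rate) @ u)


def assemble_aggregate(data: TrialDataset, horizon_years: float,
                       rate: float = 0.035,
                       discount_qalys: bool = True) -> pd.DataFrame:
    """Per-patient aggregate outcomes at a horizon.

    A total is present iff every constituent item up to the horizon is
    observed.  For costs the constituents are the periods ending at or
    before the horizon; for QALYs they are the patient's *scheduled* EQ-5D
    weeks up to the horizon, which must include the horizon week itself
    (the staggered-recruitment design means only patients whose telephone
    follow-up lands on the horizon can have a complete late QALY).
    Missing items after a patient's recorded death are zero-filled and count
    as observed.

    Returns columns: patient_id, horizon, total_cost, total_qaly,
    cost_complete, qaly_complete.
    """
    sched = data.schedule
    hw = sched.horizon_week(horizon_years)
    q_rate = rate if discount_qalys else 0.0
    base = data.baseline.set_index("patient_id")
    death_week = base["death_month"] * WEEKS_PER_MONTH if "death_month" in base \
        else pd.Series(np.nan, index=base.index)

    periods = sched.periods_within(horizon_years)
    disc = np.array([discount_factor(sched.period_midpoint(t), rate)
                     for t in periods])
    pc = data.period_costs[data.period_costs["period"].isin(periods)].copy()
    start_w = np.array([sched.period_interval(t)[0] for t in pc["period"]])
    dw = pc["patient_id"].map(death_week).to_numpy()
    dead = ~np.isnan(dw) & (dw <= start_w)
    pc.loc[dead & ~pc["observed"], "cost"] = 0.0
    pc.loc[dead, "observed"] = True

    cost_wide = pc.pivot(index="patient_id", columns="period", values="cost") \
                  .reindex(index=base.index, columns=periods)
    obs_wide = pc.pivot(index="patient_id", columns="period", values="observed") \
                 .reindex(index=base.index, columns=periods).fillna(False)
    cost_complete = obs_wide.all(axis=1).to_numpy()
    tc = (cost_wide.to_numpy() * disc).sum(axis=1)
    tc[~cost_complete] = np.nan

    eq = data.eq5d.copy()
    dw = eq["patient_id"].map(death_week).to_numpy()
    dead = ~np.isnan(dw) & (dw <= eq["week"].to_numpy())
    eq.loc[dead & ~eq["observed"], "utility"] = 0.0
    eq.loc[dead, ["observed", "scheduled"]] = True

    u_wide = eq.pivot(index="patient_id", columns="week", values="utility") \
               .reindex(base.index)
    sch_wide = eq.pivot(index="patient_id", columns="week", values="scheduled") \
                 .reindex(base.index).fillna(False).astype(bool)
    ob_wide = eq.pivot(index="patient_id", columns="week", values="observed") \
                .reindex(base.index).fillna(False).astype(bool)
    all_weeks = np.array(sorted(u_wide.columns))
    in_h = all_weeks <= hw + 1e-9
    has_h = np.any(np.isclose(all_weeks, hw))
    if not has_h:
        raise ValueError(f"horizon week {hw:g} is not on the EQ-5D grid")

    sch = sch_wide.to_numpy()[:, in_h]
    obs = ob_wide.to_numpy()[:, in_h]
    uu = u_wide.to_numpy()[:, in_h]
    weeks_h = all_weeks[in_h]
    h_col = int(np.argmin(np.abs(weeks_h - hw)))
    qaly_complete = sch[:, h_col] & np.all(~sch | obs, axis=1)

    tq = np.full(len(base), np.nan)
    # group patients by scheduled-week pattern; few distinct patterns exist
    patt = [tuple(np.nonzero(row)[0]) for row in sch]
    for p in set(patt):
        idx = np.array([i for i, q in enumerate(patt) if q == p])
        ok = idx[qaly_complete[idx]]
        if len(ok) == 0 or len(p) < 2 or h_col not in p:
            continue
        wks = weeks_h[list(p)]
        wts = _trapezium_weights(wks.astype(float), q_rate)
        tq[ok] = uu[np.ix_(ok, list(p))] @ wts
    qaly_complete &= ~np.isnan(tq)

    return pd.DataFrame({
        "patient_id": base.index.to_numpy(),
        "horizon": horizon_years,
        "total_cost": np.round(tc, 6),
        "total_qaly": np.round(tq, 6),
        "cost_complete": cost_complete,
        "qaly_complete": qaly_complete,
    })
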