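"""Shared containers: the follow-up schedule and the long-format trial dataset.

A trial is stored as three tables, mirroring how trial-based economic
evaluations are usually shipped:

* ``baseline`` — one row per patient: arm, baseline covariates, recruitment
  offset and administrative censoring time.
* ``period_costs`` — one row per patient-period: the cost accrued during the
  period, an ``observed`` flag (stochastic item missingness) and a
  ``scheduled`` flag (False once the period falls outside the patient's
  follow-up window, i.e. missing by design).
* ``eq5d`` — one row per patient-scheduled-week: the EQ-5D utility index at
  that week, with the same two flags.

All three are plain :class:`pandas.DataFrame` objects so they round-trip
through CSV without loss.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Schedule",
    "TrialDataset",
    "DEFAULT_SCHEDULE",
    "BASELINE_COVARIATES",
    "read_dataset",
    "write_dataset",
]

#: baseline covariate columns carried by every synthetic trial
BASELINE_COVARIATES = (
    "treat",
    "age",
    "size",
    "duration",
    "site",
    "ethnicity",
    "diabetes",
    "dvt_history",
    "trial_leg",
)

WEEKS_PER_MONTH = 52.0 / 12.0
WEEKS_PER_YEAR = 52.0


@dataclass(frozen=True)
class Schedule:
    """Follow-up grid: period boundaries (costs) and EQ-5D weeks.

    ``period_boundaries`` has one more entry than there are cost periods;
    period ``t`` (1-based) covers ``(boundaries[t-1], boundaries[t]]`` in
    weeks since randomisation.  The default grid gives 12 roughly-monthly
    periods over year 1 and then four yearly periods to week 260 (year 5).
    """

    period_boundaries: tuple = (0, 4, 8, 13, 17, 22, 26, 30, 35, 39, 43, 48,
                                52, 104, 156, 208, 260)
    eq5d_weeks: tuple = (0, 6, 26, 52, 104, 156, 208, 260)

    @property
    def n_periods(self) -> int:
        return len(self.period_boundaries) - 1

    def period_interval(self, t: int) -> tuple:
        """(start, end] week of 1-based period ``t``."""
        if not 1 <= t <= self.n_periods:
            raise ValueError(f"period index {t} out of range 1..{self.n_periods}")
        return self.period_boundaries[t - 1], self.period_boundaries[t]

    def period_end(self, t: int) -> float:
        return self.period_interval(t)[1]

    def period_midpoint(self, t: int) -> float:
        a, b = self.period_interval(t)
        return 0.5 * (a + b)

    @staticmethod
    def horizon_week(horizon_years: float) -> float:
        return horizon_years * WEEKS_PER_YEAR

    def periods_within(self, horizon_years: float) -> list:
        """1-based period indices whose interval ends at or before the horizon."""
        hw = self.horizon_week(horizon_years)
        return [t for t in range(1, self.n_periods + 1) if self.period_end(t) <= hw + 1e-9]

    def eq5d_weeks_within(self, horizon_years: float) -> list:
        hw = self.horizon_week(horizon_years)
        return [w for w in self.eq5d_weeks if w <= hw + 1e-9]

    def telephone_week(self, censor_week: float) -> Optional[int]:
        """Latest post-year-1 EQ-5D grid week at or before the censoring week.

        Returns ``None`` when no post-year-1 grid week has been reached
        (cannot occur under the default design, where follow-up is >= 2 y).
        """
        late = [w for w in self.eq5d_weeks if w > 52 and w <= censor_week + 1e-9]
        return max(late) if late else None


DEFAULT_SCHEDULE = Schedule()


@dataclass
class TrialDataset:
    """Baseline + longitudinal cost/EQ-5D records with observed flags.

    ``shadow_costs`` / ``shadow_eq5d`` hold the pre-missingness truth after
    :func:`ceamiss.simulate.impose_missingness`; they exist purely so that
    estimator recovery can be scored and are never consulted by estimators.
    """

    baseline: pd.DataFrame
    period_costs: pd.DataFrame
    eq5d: pd.DataFrame
    schedule: Schedule = field(default_factory=Schedule)
    shadow_costs: Optional[pd.DataFrame] = None
    shadow_eq5d: Optional[pd.DataFrame] = None

    @property
    def n_patients(self) -> int:
        return len(self.baseline)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.baseline["patient_id"].to_numpy()

    def copy(self) -> "TrialDataset":
        return TrialDataset(
            baseline=self.baseline.copy(),
            period_costs=self.period_costs.copy(),
            eq5d=self.eq5d.copy(),
            schedule=self.schedule,
            shadow_costs=None if self.shadow_costs is None else self.shadow_costs.copy(),
            shadow_eq5d=None if self.shadow_eq5d is None else self.shadow_eq5d.copy(),
        )

    def eq5d0(self) -> pd.Series:
        """Baseline (week-0) utility per patient, aligned with ``baseline``."""
        wk0 = self.eq5d[self.eq5d["week"] == 0].set_index("patient_id")["utility"]
        return wk0.reindex(self.baseline["patient_id"]).reset_index(drop=True)

    def validate(self) -> None:
        """Raise ``ValueError`` on any structural-invariant violation."""
        if self.baseline["patient_id"].duplicated().any():
            raise ValueError("duplicate patient_id in baseline")
        pc_keys = self.period_costs[["patient_id", "period"]]
        if pc_keys.duplicated().any():
            raise ValueError("duplicate (patient, period) keys in period_costs")
        eq_keys = self.eq5d[["patient_id", "week"]]
        if eq_keys.duplicated().any():
            raise ValueError("duplicate (patient, week) keys in eq5d")
        known = set(self.baseline["patient_id"])
        if not set(pc_keys["patient_id"]).issubset(known):
            raise ValueError("period_costs references unknown patients")
        if not set(eq_keys["patient_id"]).issubset(known):
            raise ValueError("eq5d references unknown patients")
        obs_cost = self.period_costs.loc[self.period_costs["observed"], "cost"]
        if obs_cost.isna().any():
            raise ValueError("observed period cost is NaN")
        if (obs_cost < 0).any():
            raise ValueError("negative observed period cost")
        obs_u = self.eq5d.loc[self.eq5d["observed"], "utility"]
        if obs_u.isna().any():
            raise ValueError("observed utility is NaN")
        if ((obs_u < -0.594 - 1e-9) | (obs_u > 1 + 1e-9)).any():
            raise ValueError("observed utility outside [-0.594, 1]")


# ---------------------------------------------------------------------------
# delimited-text round trip
# ---------------------------------------------------------------------------

def write_dataset(data: TrialDataset, outdir) -> None:
    """Write ``baseline.csv``, ``costs_long.csv``, ``eq5d_long.csv`` (and the
    shadow tables when present, under ``shadow_`` prefixes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.baseline.to_csv(outdir / "baseline.csv", index=False)
    data.period_costs.to_csv(outdir / "costs_long.csv", index=False)
    data.eq5d.to_csv(outdir / "eq5d_long.csv", index=False)
    if data.shadow_costs is not None:
        data.shadow_costs.to_csv(outdir / "shadow_costs_long.csv", index=False)
    if data.shadow_eq5d is not None:
        data.shadow_eq5d.to_csv(outdir / "shadow_eq5d_long.csv", index=False)
    sched = pd.DataFrame({
        "kind": ["period_boundary"] * len(data.schedule.period_boundaries)
                + ["eq5d_week"] * len(data.schedule.eq5d_weeks),
        "week": list(data.schedule.period_boundaries) + list(data.schedule.eq5d_weeks),
    })
    sched.to_csv(outdir / "schedule.csv", index=False)


def read_dataset(indir) -> TrialDataset:
    indir = Path(indir)
    baseline = pd.read_csv(indir / "baseline.csv")
    costs = pd.read_csv(indir / "costs_long.csv")
    eq5d = pd.read_csv(indir / "eq5d_long.csv")
    for tbl in (costs, eq5d):
        for col in ("observed", "scheduled"):
            if col in tbl.columns:
                tbl[col] = tbl[col].astype(bool)
    sched_path = indir / "schedule.csv"
    if sched_path.exists():
        sched = pd.read_csv(sched_path)
        schedule = Schedule(
            period_boundaries=tuple(sched.loc[sched["kind"] == "period_boundary", "week"].astype(int)),
            eq5d_weeks=tuple(sched.loc[sched["kind"] == "eq5d_week", "week"].astype(int)),
        )
    else:
        schedule = DEFAULT_SCHEDULE
    shadow_costs = shadow_eq5d = None
    if (indir / "shadow_costs_long.csv").exists():
        shadow_costs = pd.read_csv(indir / "shadow_costs_long.csv")
    if (indir / "shadow_eq5d_long.csv").exists():
        shadow_eq5d = pd.read_csv(indir / "shadow_eq5d_long.csv")
    ds = TrialDataset(baseline=baseline, period_costs=costs, eq5d=eq5d,
                      schedule=schedule, shadow_costs=shadow_costs,
                      shadow_eq5d=shadow_eq5d)
    ds.validate()
    return ds
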