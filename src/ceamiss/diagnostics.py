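"""Missingness description and modelling.

Two tools: the four-cell missing-pattern table of aggregate totals
(complete/missing cost x complete/missing EQ-5D), and the item-level
logistic regression of the missing indicator on treatment, baseline
covariates and follow-up week.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import TrialDataset
from .simulate import AGE_CENTER, DURATION_CENTER, SIZE_CENTER

__all__ = ["MissingnessFit", "pattern_table", "fit_missingness_logit"]

PATTERN_LABELS = [
    "complete cost, complete EQ-5D",
    "complete cost, missing EQ-5D",
    "missing cost, complete EQ-5D",
    "missing cost, missing EQ-5D",
]


def pattern_table(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Four-cell counts and percentages of the aggregate missingness pattern.

    ``outcomes`` is an assembled aggregate table (see
    :func:`ceamiss.outcomes.assemble_aggregate`) with ``cost_complete`` and
    ``qaly_complete`` flags.  Percentages sum to 100 up to rounding.
    """
    if len(outcomes) == 0:
        raise ValueError("empty aggregate table")
    cc = outcomes["cost_complete"].to_numpy(dtype=bool)
    qc = outcomes["qaly_complete"].to_numpy(dtype=bool)
    counts = [int((cc & qc).sum()), int((cc & ~qc).sum()),
              int((~cc & qc).sum()), int((~cc & ~qc).sum())]
    n = len(outcomes)
    return pd.DataFrame({
        "pattern": PATTERN_LABELS,
        "n": counts,
        "percent": [round(100.0 * c / n, 1) for c in counts],
    })


@dataclass
class MissingnessFit:
    """Item-level logistic fit of the missing indicator."""

    target: str
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    converged: bool
    separation: bool
    n_items: int
    missing_fraction: float
    fitted_mean: float  # mean fitted probability (= missing_fraction at MLE)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse,
                             "z": self.zvalues})


def _item_table(data: TrialDataset, target: str,
                scheduled_only: bool) -> pd.DataFrame:
    if target == "eq5d":
        items = data.eq5d.copy()
        items["week"] = items["week"].astype(float)
        items = items[items["week"] > 0]  # baseline utility is never missing
    elif target == "cost":
        items = data.period_costs.copy()
        end = {t: data.schedule.period_end(t)
               for t in range(1, data.schedule.n_periods + 1)}
        items["week"] = items["period"].map(end).astype(float)
    else:
        raise ValueError("target must be 'cost' or 'eq5d'")
    if scheduled_only:
        items = items[items["scheduled"]]
    items = items.merge(data.baseline, on="patient_id", how="left")
    items["missing"] = (~items["observed"]).astype(float)
    return items


def fit_missingness_logit(data: TrialDataset, target: str = "eq5d",
                          scheduled_only: bool = True) -> MissingnessFit:
    """ML logistic fit of item missingness on TREAT, DURATION, AGE, SIZE,
    SITE (factor) and WEEK (factor), with an intercept.

    ``scheduled_only`` restricts to items within the design schedule, so the
    fit describes the stochastic (MAR) layer rather than the deterministic
    censoring pattern; set it False to describe both layers together.
    Complete separation is detected and flagged rather than penalised.
    """
    items = _item_table(data, target, scheduled_only)
    y = items["missing"].to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one missing and one observed item")

    X = pd.DataFrame({
        "intercept": 1.0,
        "treat": items["treat"].astype(float),
        "duration": items["duration"] - DURATION_CENTER,
        "age": items["age"] - AGE_CENTER,
        "size": items["size"] - SIZE_CENTER,
    })
    site_d = pd.get_dummies(items["site"], prefix="site", drop_first=True,
                            dtype=float)
    week_d = pd.get_dummies(items["week"].astype(int), prefix="week",
                            drop_first=True, dtype=float)
    X = pd.concat([X.reset_index(drop=True), site_d.reset_index(drop=True),
                   week_d.reset_index(drop=True)], axis=1)

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
        for w in caught:
            if "separation" in str(w.message).lower() or \
               "convergence" in str(w.message).lower():
                separation = True
    if not np.all(np.isfinite(res.params)) or np.any(np.abs(res.params) > 30):
        separation = True
        warnings.warn(f"possible separation in {target} missingness logit",
                      stacklevel=2)
    return MissingnessFit(
        target=target,
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        zvalues=pd.Series(res.tvalues, index=X.columns),
        converged=bool(res.converged),
        separation=separation,
        n_items=len(y),
        missing_fraction=float(y.mean()),
        fitted_mean=float(res.fittedvalues.mean()),
    )
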