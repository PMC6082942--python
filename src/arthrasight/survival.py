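"""Kaplan-Meier analysis of transition from arthralgia to RA.

Arthralgia patients are grouped by how many of the six algorithm parameters
(three clinical symptom items, survivin, any antibody, and female >50 years
or elevated CRP depending on the variant) they carry at the first visit:
"high" means at least the boundary (default 4) positive parameters, "low"
fewer.  RA-free survival over the 48-month horizon is estimated per group by
the product-limit method, and the 48-month positive predictive value and the
group-wise odds ratio quantify the separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import Cohort, HORIZON_MONTHS
from .imputation import subset_completions
from .scoring import CompositeModel, component_matrix, composite_score
from .screening import TwoByTwo, odds_ratio, OddsRatioResult
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "SurvivalData",
    "KMCurve",
    "km_estimate",
    "group_by_param_count",
    "horizon_ppv",
    "MODEL_VARIANT_A",
    "MODEL_VARIANT_B",
]

#: Variant A: 3 clinical items + survivin + any antibody + female >50y.
MODEL_VARIANT_A = CompositeModel(
    ("s5", "s10", "s11", "survivin_pos", "any_ab", "female_over_50"),
    name="6 parameters (female >50y)",
)
#: Variant B: the female >50y parameter replaced by elevated CRP.
MODEL_VARIANT_B = CompositeModel(
    ("s5", "s10", "s11", "survivin_pos", "any_ab", "crp_high"),
    name="6 parameters (CRP)",
)


@dataclass
class SurvivalData:
    """Per-patient time (months, (0, horizon]), event flag and risk group."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray  # "low" (< boundary parameters) or "high" (>= boundary)
    boundary: int = 4

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        self.group = np.asarray(self.group, dtype=object)
        if not (len(self.time) == len(self.event) == len(self.group)):
            raise ValueError("time, event and group must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")

    def subset(self, group: str) -> Tuple[np.ndarray, np.ndarray]:
        sel = self.group == group
        return self.time[sel], self.event[sel]


@dataclass
class KMCurve:
    """Product-limit survival estimate with at-risk counts.

    ``survival[i]`` is S(t) just after ``event_times[i]``; S(0) = 1.
    ``greenwood_var`` is the Greenwood variance estimate at each time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_var: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function lookup of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one group.

    Ties are aggregated at identical times.  Censored observations reduce
    the risk set after their time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if len(time) < 1:
        raise ValueError("need at least one observation")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    table = table[table.index > 0]
    times = table.index.to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    d = table["observed"].to_numpy(dtype=float)
    surv = np.array([float(kmf.predict(t)) for t in times])
    # Greenwood: Var S(t) = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
    gvar = surv**2 * np.cumsum(terms)
    gvar[~np.isfinite(gvar)] = np.nan
    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=at_risk.astype(int),
        n_events=d.astype(int),
        greenwood_var=gvar,
    )


def group_by_param_count(
    cohort: Cohort,
    model6: CompositeModel,
    completions: Optional[List[np.ndarray]] = None,
    boundary: int = 4,
) -> SurvivalData:
    """Partition the arthralgia stratum by positive-parameter count.

    ``model6`` must have exactly six components.  Patients with at least
    ``boundary`` positive parameters form the high-risk group, the rest the
    low-risk group; the partition is exhaustive and exclusive.  Progressors
    contribute an event at their month of RA; non-progressors are censored
    at the horizon.
    """
    if len(model6) != 6:
        raise ValueError(f"model must have exactly 6 components, got {len(model6)}")
    df = cohort.df
    if "group" not in df.columns:
        raise ValueError("cohort is not labelled; run label_pre_ra first")
    mask = df["group"].isin(["pre-RA", "arthralgia"]).to_numpy()
    sub = df[mask].reset_index(drop=True)
    values = component_matrix(sub, subset_completions(completions, mask))
    counts = composite_score(values, model6)

    event = (sub["group"] == "pre-RA").to_numpy()
    months = sub["months_to_ra"].to_numpy(dtype=float)
    time = np.where(event, months, cohort.horizon_months)
    time = np.maximum(time, 0.5)  # events recorded at month 0 sit in (0, 1)
    risk = np.where(counts >= boundary, "high", "low")
    return SurvivalData(time=time, event=event, group=risk, boundary=boundary)


def horizon_ppv(
    data: SurvivalData, horizon: int = HORIZON_MONTHS
) -> dict:
    """48-month PPV of the high-parameter group, with CI and group OR.

    PPV is the simple event proportion in the high group by the horizon;
    when early censoring exists in the high group the complementary
    product-limit estimate 1 - S(horizon) is reported alongside and the
    result is flagged.  The OR contrasts event odds, high vs low group.
    """
    n_high = int((data.group == "high").sum())
    n_low = int((data.group == "low").sum())
    if n_high == 0:
        raise ValueError("high-parameter group is empty; cannot compute PPV")
    if n_low == 0:
        raise ValueError("low-parameter group is empty; cannot compute OR")

    def events_by_horizon(group: str) -> int:
        t, e = data.subset(group)
        return int((e & (t <= horizon)).sum())

    ev_high = events_by_horizon("high")
    ev_low = events_by_horizon("low")
    ppv = ev_high / n_high
    ppv_lo, ppv_hi = proportion_confint(ev_high, n_high, alpha=0.05, method="wilson")

    t_high, e_high = data.subset("high")
    early_censoring = bool(np.any(~e_high & (t_high < horizon)))
    km_ppv = None
    if early_censoring:
        km_ppv = 1.0 - km_estimate(t_high, e_high).survival_at(horizon)

    or_result: OddsRatioResult = odds_ratio(
        TwoByTwo(a=ev_high, b=n_high - ev_high, c=ev_low, d=n_low - ev_low)
    )
    return {
        "n_high": n_high,
        "n_low": n_low,
        "events_high": ev_high,
        "events_low": ev_low,
        "ppv": ppv,
        "ppv_ci": (float(ppv_lo), float(ppv_hi)),
        "ppv_low_group": ev_low / n_low,
        "odds_ratio": or_result,
        "early_censoring": early_censoring,
        "km_event_probability": km_ppv,
    }
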