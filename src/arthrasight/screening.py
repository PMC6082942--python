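"""2x2 association analysis: odds ratios, confidence intervals, screening.

Implements the contingency machinery the pipeline is built on: 2x2 tables,
odds ratios with Woolf (log-normal) or mid-P exact confidence intervals,
chi-square / Fisher / mid-P p-values, the OR > 2 symptom screening rule for
the pre-RA versus remaining-arthralgia contrast, and the per-marker symptom
adherence table over the arthralgia stratum.

Conventions.  OR orientation is exposure = symptom or marker, outcome =
later-diagnosed group.  Tables with a zero cell receive the
Haldane-Anscombe +0.5 correction (flagged on the result).  When several
imputed completions are supplied, the point estimate is the mean log-OR
across completions and the variance combines by Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .cohort import Cohort, MARKER_COLUMNS, N_SYMPTOMS, SYMPTOM_COLUMNS, add_binary_markers
from .imputation import pool_estimates, subset_completions

__all__ = [
    "TwoByTwo",
    "OddsRatioResult",
    "ScreenResult",
    "two_by_two",
    "odds_ratio",
    "screen_symptoms",
    "biomarker_adherence",
]

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class TwoByTwo:
    """Counts a = exposed & outcome, b = exposed & not, c = unexposed &
    outcome, d = unexposed & not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class OddsRatioResult:
    or_hat: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    continuity_corrected: bool
    table: Optional[TwoByTwo] = None


def two_by_two(exposure: Sequence, outcome: Sequence) -> TwoByTwo:
    """Cross-tabulate two equal-length binary vectors (no missing values)."""
    e = np.asarray(exposure, dtype=float)
    o = np.asarray(outcome, dtype=float)
    if e.shape != o.shape or e.ndim != 1:
        raise ValueError("exposure and outcome must be equal-length 1-d vectors")
    if np.isnan(e).any() or np.isnan(o).any():
        raise ValueError("vectors must not contain missing values")
    e = e.astype(bool)
    o = o.astype(bool)
    return TwoByTwo(
        a=int((e & o).sum()),
        b=int((e & ~o).sum()),
        c=int((~e & o).sum()),
        d=int((~e & ~o).sum()),
    )


def _pearson_chi2_p(t: TwoByTwo, yates: bool = False) -> float:
    r1, r2 = t.a + t.b, t.c + t.d
    c1, c2 = t.a + t.c, t.b + t.d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    diff = abs(t.a * t.d - t.b * t.c)
    if yates:
        diff = max(diff - t.n / 2, 0.0)
    chi2 = t.n * diff**2 / (r1 * r2 * c1 * c2)
    return float(stats.chi2.sf(chi2, 1))


def _hypergeom_midp_p(t: TwoByTwo) -> float:
    r1, c1 = t.a + t.b, t.a + t.c
    if min(r1, t.n - r1, c1, t.n - c1) == 0:
        return 1.0
    dist = stats.hypergeom(t.n, c1, r1)
    lo = dist.cdf(t.a) - 0.5 * dist.pmf(t.a)
    hi = dist.sf(t.a - 1) - 0.5 * dist.pmf(t.a)
    return float(min(1.0, 2 * min(lo, hi)))


def _p_value(t: TwoByTwo, p_method: str) -> float:
    if p_method == "pearson":
        return _pearson_chi2_p(t)
    if p_method == "yates":
        return _pearson_chi2_p(t, yates=True)
    if p_method == "fisher":
        return float(stats.fisher_exact([[t.a, t.b], [t.c, t.d]])[1])
    if p_method == "midp":
        return _hypergeom_midp_p(t)
    raise ValueError(f"unknown p-value method {p_method!r}")


def _midp_exact_ci(t: TwoByTwo, alpha: float = 0.05) -> tuple:
    """Conditional mid-P exact CI for the odds ratio.

    Conditioned on both margins, the exposed-outcome cell follows Fisher's
    noncentral hypergeometric distribution with the odds ratio as its
    noncentrality; the bounds solve the mid-P tail equations.
    """
    r1, c1 = t.a + t.b, t.a + t.c
    if min(r1, t.n - r1, c1, t.n - c1) == 0:
        return 0.0, np.inf
    lo_support = max(0, r1 + c1 - t.n)
    hi_support = min(r1, c1)

    def upper_tail(log_psi: float) -> float:
        d = stats.nchypergeom_fisher(t.n, c1, r1, np.exp(log_psi))
        return d.sf(t.a) + 0.5 * d.pmf(t.a) - alpha / 2

    def lower_tail(log_psi: float) -> float:
        d = stats.nchypergeom_fisher(t.n, c1, r1, np.exp(log_psi))
        return d.cdf(t.a - 1) + 0.5 * d.pmf(t.a) - alpha / 2

    lim = 50.0
    # lower bound: as psi -> 0 the upper tail vanishes
    if t.a == lo_support:
        ci_low = 0.0
    else:
        ci_low = float(np.exp(brentq(upper_tail, -lim, lim, xtol=1e-10)))
    if t.a == hi_support:
        ci_high = np.inf
    else:
        ci_high = float(np.exp(brentq(lower_tail, -lim, lim, xtol=1e-10)))
    return ci_low, ci_high


def odds_ratio(
    t: TwoByTwo,
    method: str = "woolf",
    p_method: str = "pearson",
    alpha: float = 0.05,
) -> OddsRatioResult:
    """Odds ratio with 95% CI and association p-value for a 2x2 table.

    method "woolf": OR = ad/bc, CI = exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d));
    a zero cell triggers the Haldane-Anscombe +0.5 correction of all four
    cells (flagged).  method "midp_exact": cross-product OR with conditional
    mid-P exact bounds.  p_method is one of pearson (uncorrected chi-square,
    default), yates, fisher, midp.
    """
    p_value = _p_value(t, p_method)
    corrected = min(t.a, t.b, t.c, t.d) == 0
    if method == "woolf":
        a, b, c, d = (x + 0.5 if corrected else float(x) for x in (t.a, t.b, t.c, t.d))
        or_hat = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = stats.norm.ppf(1 - alpha / 2)
        ci_low = float(or_hat * np.exp(-z * se))
        ci_high = float(or_hat * np.exp(z * se))
    elif method == "midp_exact":
        a, b, c, d = (x + 0.5 if corrected else float(x) for x in (t.a, t.b, t.c, t.d))
        or_hat = (a * d) / (b * c)
        ci_low, ci_high = _midp_exact_ci(t, alpha)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return OddsRatioResult(
        or_hat=float(or_hat),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_value,
        method=method,
        continuity_corrected=corrected,
        table=t,
    )


def _pooled_or(
    tables: List[TwoByTwo], method: str, p_method: str
) -> OddsRatioResult:
    """Combine one symptom's 2x2 tables across imputed completions.

    Mean log-OR point estimate; Rubin's rules on the Woolf log-OR variance;
    two-sided normal p from the pooled z.  With a single table this defers
    to :func:`odds_ratio` unchanged.
    """
    if len(tables) == 1:
        return odds_ratio(tables[0], method=method, p_method=p_method)
    per = []
    corrected = False
    for t in tables:
        corr = min(t.a, t.b, t.c, t.d) == 0
        corrected = corrected or corr
        a, b, c, d = (x + 0.5 if corr else float(x) for x in (t.a, t.b, t.c, t.d))
        per.append((np.log(a * d / (b * c)), 1 / a + 1 / b + 1 / c + 1 / d))
    log_or, var = pool_estimates(per)
    se = np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(log_or) / se))
    return OddsRatioResult(
        or_hat=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        p_value=p,
        method=method,
        continuity_corrected=corrected,
        table=tables[0],
    )


@dataclass
class ScreenResult:
    """Per-symptom odds ratios for a group contrast plus the selected set."""

    results: Dict[int, OddsRatioResult]
    threshold: float
    selected: List[int] = field(init=False)

    def __post_init__(self) -> None:
        self.selected = sorted(
            i for i, r in self.results.items() if r.or_hat > self.threshold
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in sorted(self.results):
            r = self.results[i]
            t = r.table
            rows.append(
                {
                    "symptom": i,
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                    "or": r.or_hat,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p": r.p_value,
                    "selected": i in self.selected,
                }
            )
        return pd.DataFrame(rows)


def _symptom_tables(
    df: pd.DataFrame,
    outcome: np.ndarray,
    completions: Optional[List[np.ndarray]],
) -> List[List[TwoByTwo]]:
    """One list of per-completion 2x2 tables per symptom item."""
    if completions is None:
        mat = df[list(SYMPTOM_COLUMNS)].to_numpy(dtype=float)
        if np.isnan(mat).any():
            raise ValueError(
                "symptom matrix contains missing cells; impute first or pass completions"
            )
        completions = [mat]
    out = []
    for i in range(N_SYMPTOMS):
        out.append([two_by_two(comp[:, i], outcome) for comp in completions])
    return out


def screen_symptoms(
    cohort: Cohort,
    completions: Optional[List[np.ndarray]] = None,
    threshold: float = 2.0,
    method: str = "woolf",
    p_method: str = "pearson",
) -> ScreenResult:
    """OR > threshold screening of the 13 items, pre-RA vs remaining arthralgia.

    The cohort must be labelled (see :func:`arthrasight.cohort.label_pre_ra`).
    ``completions`` are imputed completions of the *arthralgia-stratum* rows
    (first-visit arthralgia, in cohort order); omitted, the observed matrix
    is used and must be complete.
    """
    df = cohort.df
    if "group" not in df.columns:
        raise ValueError("cohort is not labelled; run label_pre_ra first")
    mask = df["group"].isin(["pre-RA", "arthralgia"]).to_numpy()
    sub = df[mask].reset_index(drop=True)
    outcome = (sub["group"] == "pre-RA").to_numpy()
    if outcome.all() or not outcome.any():
        raise ValueError("contrast requires both pre-RA and remaining arthralgia patients")
    tables = _symptom_tables(sub, outcome, subset_completions(completions, mask))
    results = {
        i + 1: _pooled_or(tables[i], method, p_method) for i in range(N_SYMPTOMS)
    }
    return ScreenResult(results=results, threshold=threshold)


def biomarker_adherence(
    cohort: Cohort,
    marker: str,
    completions: Optional[List[np.ndarray]] = None,
    method: str = "woolf",
    p_method: str = "pearson",
) -> pd.DataFrame:
    """Symptom adherence of one serological marker over the arthralgia stratum.

    For each of the 13 items, the OR with exposure = marker and outcome =
    symptom among first-visit arthralgia patients (pre-RA included), plus the
    marker-positive / negative group sizes.
    """
    if marker not in MARKER_COLUMNS:
        raise ValueError(f"unknown marker {marker!r}; choose from {MARKER_COLUMNS}")
    df = cohort.df
    if "group" not in df.columns:
        raise ValueError("cohort is not labelled; run label_pre_ra first")
    mask = df["group"].isin(["pre-RA", "arthralgia"]).to_numpy()
    sub = df[mask].reset_index(drop=True)
    if marker not in sub.columns:
        sub = add_binary_markers(sub)
    exposure = sub[marker].to_numpy(dtype=bool)
    if exposure.all() or not exposure.any():
        raise ValueError(f"marker {marker!r} is monomorphic in the arthralgia stratum")

    completions = subset_completions(completions, mask)
    if completions is None:
        mat = sub[list(SYMPTOM_COLUMNS)].to_numpy(dtype=float)
        if np.isnan(mat).any():
            raise ValueError(
                "symptom matrix contains missing cells; impute first or pass completions"
            )
        completions = [mat]

    rows = []
    for i in range(N_SYMPTOMS):
        tabs = [two_by_two(exposure, comp[:, i]) for comp in completions]
        r = _pooled_or(tabs, method, p_method)
        rows.append(
            {
                "symptom": i + 1,
                "or": r.or_hat,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p_value,
                "n_pos": int(exposure.sum()),
                "n_neg": int((~exposure).sum()),
            }
        )
    return pd.DataFrame(rows)
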