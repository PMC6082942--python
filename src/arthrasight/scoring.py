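"""Unweighted composite risk scores and their diagnostic evaluation.

A composite model is an ordered list of binary components (clinical symptom
items and/or serological markers); the patient score is simply the count of
positive components — no weighting.  This module computes ROC curves and
AUC (trapezoidal, equal to the tie-corrected Mann-Whitney statistic),
operating-point diagnostics (sensitivity, specificity, PPV, NPV with Wilson
or mid-P exact confidence intervals), marker enrichment of a clinical base
model, and an audit tool that reconstructs the integer confusion matrix
behind printed, rounded sensitivity/specificity pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort, MARKER_COLUMNS, SYMPTOM_COLUMNS, add_binary_markers
from .imputation import subset_completions

__all__ = [
    "CompositeModel",
    "RocCurve",
    "DiagnosticMetrics",
    "composite_score",
    "component_matrix",
    "roc",
    "metrics_at_cut",
    "metrics_from_counts",
    "confusion_from_rounded",
    "enrich_model",
    "STANDARD_ENRICHMENTS",
    "round_half_up",
]

VALID_COMPONENTS = tuple(SYMPTOM_COLUMNS) + tuple(MARKER_COLUMNS)

#: The six evaluated models: the clinical base plus each marker combination,
#: in fixed presentation order.
STANDARD_ENRICHMENTS: Tuple[Tuple[str, Tuple[str, ...]], ...] = (
    ("3 clinical", ()),
    ("+ Survivin+CRP", ("survivin_pos", "crp_high")),
    ("+ Survivin+AnyAB", ("survivin_pos", "any_ab")),
    ("+ CRP+AnyAB", ("crp_high", "any_ab")),
    ("+ Survivin+CRP+AnyAB", ("survivin_pos", "crp_high", "any_ab")),
    ("+ Survivin+AnyAB+female >50y", ("survivin_pos", "any_ab", "female_over_50")),
)


def round_half_up(x: float, dp: int = 1) -> float:
    """Decimal half-up rounding, matching printed-table conventions."""
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompositeModel:
    """Ordered, unique binary components defining an unweighted count score."""

    components: Tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("model must have at least one component")
        if len(set(comps)) != len(comps):
            raise ValueError("model components must be unique")
        for c in comps:
            if c not in VALID_COMPONENTS:
                raise ValueError(f"unknown component {c!r}")
        if not self.name:
            object.__setattr__(self, "name", "+".join(comps))

    def __len__(self) -> int:
        return len(self.components)


def composite_score(values: pd.DataFrame, model: CompositeModel) -> np.ndarray:
    """Unweighted score: the count of positive components per patient.

    ``values`` must carry one resolvable binary column per component (no
    missing cells — impute first).
    """
    cols = []
    for c in model.components:
        if c not in values.columns:
            raise ValueError(f"component {c!r} not present in the data")
        col = values[c].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(f"component {c!r} contains missing values; impute first")
        cols.append(col.astype(bool))
    return np.sum(cols, axis=0).astype(int)


def component_matrix(
    df: pd.DataFrame, completions: Optional[List[np.ndarray]] = None
) -> pd.DataFrame:
    """Resolve all scoreable components for a patient subset.

    Markers are dichotomised from raw serology if absent.  When imputed
    completions of the symptom matrix are supplied, symptom items are pooled
    by per-cell majority vote across completions (ties resolved toward
    present) before scoring.
    """
    out = df if all(m in df.columns for m in MARKER_COLUMNS) else add_binary_markers(df)
    out = out.copy()
    if completions is not None:
        stacked = np.mean([c for c in completions], axis=0)
        voted = (stacked >= 0.5).astype(float)
        out[list(SYMPTOM_COLUMNS)] = voted
    return out


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: one operating point per distinct score threshold."""

    thresholds: np.ndarray  # descending cut-points; score >= cut is positive
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_p: float
    auc_ci: Tuple[float, float]


def roc(scores: Sequence, labels: Sequence) -> RocCurve:
    """ROC curve, trapezoidal AUC, normal-approximation p, Hanley-McNeil CI.

    Ties are grouped into single operating points; the trapezoidal AUC then
    equals the tie-corrected Mann-Whitney U / (n1 * n0).  The p-value tests
    AUC = 0.5 via the normal approximation to U with tie correction.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d vectors")
    if np.isnan(s).any() or np.isnan(y).any():
        raise ValueError("scores and labels must not contain missing values")
    y = y.astype(bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    thresholds = np.sort(np.unique(s))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        pos = s >= t
        tpr.append(float((pos & y).sum() / n1))
        fpr.append(float((pos & ~y).sum() / n0))
    tpr = np.array(tpr)
    fpr = np.array(fpr)
    auc = float(np.trapezoid(tpr, fpr))

    # Normal approximation to Mann-Whitney U with tie correction.
    n = n1 + n0
    u = auc * n1 * n0
    _, tie_counts = np.unique(s, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var_u = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        p = 1.0
    else:
        p = float(2 * stats.norm.sf(abs(u - n1 * n0 / 2) / np.sqrt(var_u)))

    # Hanley-McNeil standard error for the AUC confidence interval.
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    se = np.sqrt(
        max(
            (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2))
            / (n1 * n0),
            0.0,
        )
    )
    z = stats.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc, auc_p=p, auc_ci=ci)


def _midp_binom_ci(k: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Mid-P exact confidence interval for a binomial proportion."""
    from scipy.optimize import brentq

    def upper_tail(p: float) -> float:
        d = stats.binom(n, p)
        return d.sf(k) + 0.5 * d.pmf(k) - alpha / 2

    def lower_tail(p: float) -> float:
        d = stats.binom(n, p)
        return d.cdf(k - 1) + 0.5 * d.pmf(k) - alpha / 2

    lo = 0.0 if k == 0 else float(brentq(upper_tail, 1e-12, 1 - 1e-12, xtol=1e-12))
    hi = 1.0 if k == n else float(brentq(lower_tail, 1e-12, 1 - 1e-12, xtol=1e-12))
    return lo, hi


def _prop_ci(k: int, n: int, ci_method: str) -> Tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    if ci_method == "wilson":
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        # guard float round-off at the boundaries so the interval always
        # contains k/n and stays inside [0, 1]
        return max(0.0, min(float(lo), k / n)), min(1.0, max(float(hi), k / n))
    if ci_method == "midp_exact":
        return _midp_binom_ci(k, n)
    raise ValueError(f"unknown ci_method {ci_method!r}")


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Confusion counts and derived proportions at one operating cut."""

    cut: int
    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: Tuple[float, float]
    specificity_ci: Tuple[float, float]
    ppv_ci: Tuple[float, float]
    npv_ci: Tuple[float, float]
    ci_method: str


def metrics_from_counts(
    tp: int, fn: int, fp: int, tn: int, cut: int = 0, ci_method: str = "wilson"
) -> DiagnosticMetrics:
    """Diagnostic metrics from an explicit confusion matrix."""
    n_pos_test = tp + fp
    n_neg_test = fn + tn
    return DiagnosticMetrics(
        cut=cut,
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (fp + tn) if fp + tn else float("nan"),
        ppv=tp / n_pos_test if n_pos_test else float("nan"),
        npv=tn / n_neg_test if n_neg_test else float("nan"),
        sensitivity_ci=_prop_ci(tp, tp + fn, ci_method),
        specificity_ci=_prop_ci(tn, fp + tn, ci_method),
        ppv_ci=_prop_ci(tp, n_pos_test, ci_method) if n_pos_test else (0.0, 1.0),
        npv_ci=_prop_ci(tn, n_neg_test, ci_method) if n_neg_test else (0.0, 1.0),
        ci_method=ci_method,
    )


def metrics_at_cut(
    scores: Sequence, labels: Sequence, cut: int, ci_method: str = "wilson"
) -> DiagnosticMetrics:
    """Operating-point diagnostics: positive iff score >= cut."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float).astype(bool)
    if not y.any() or y.all():
        raise ValueError("both classes must be present")
    if not (0 <= cut <= s.max() + 1):
        raise ValueError(f"cut must lie in [0, {int(s.max()) + 1}]")
    pos = s >= cut
    return metrics_from_counts(
        tp=int((pos & y).sum()),
        fn=int((~pos & y).sum()),
        fp=int((pos & ~y).sum()),
        tn=int((~pos & ~y).sum()),
        cut=cut,
        ci_method=ci_method,
    )


def confusion_from_rounded(
    sens_pct: float, spec_pct: float, n_events: int, n_nonevents: int
) -> dict:
    """Invert printed 1-dp sensitivity/specificity percentages to counts.

    Returns every integer (tp, tn) pair whose exact percentages round
    (half-up, 1 dp) to the printed values, with a uniqueness flag; an empty
    solution list is flagged infeasible.  Used to audit published tables
    whose underlying counts were not printed.
    """
    if n_events < 1 or n_nonevents < 1:
        raise ValueError("n_events and n_nonevents must be >= 1")
    tps = [
        tp
        for tp in range(n_events + 1)
        if round_half_up(100 * tp / n_events, 1) == round_half_up(sens_pct, 1)
    ]
    tns = [
        tn
        for tn in range(n_nonevents + 1)
        if round_half_up(100 * tn / n_nonevents, 1) == round_half_up(spec_pct, 1)
    ]
    solutions = [
        {"tp": tp, "fn": n_events - tp, "fp": n_nonevents - tn, "tn": tn}
        for tp in tps
        for tn in tns
    ]
    return {
        "solutions": solutions,
        "unique": len(solutions) == 1,
        "feasible": len(solutions) > 0,
    }


def enrich_model(
    base: CompositeModel,
    cohort: Cohort,
    completions: Optional[List[np.ndarray]] = None,
    cut: int = 3,
    enrichments: Tuple[Tuple[str, Tuple[str, ...]], ...] = STANDARD_ENRICHMENTS,
    ci_method: str = "wilson",
) -> pd.DataFrame:
    """Evaluate the clinical base model and its marker-enriched variants.

    Rows follow ``enrichments`` order: the base alone, then the base plus
    each stated marker combination, all at operating cut ``cut`` on the
    pre-RA vs remaining-arthralgia contrast.  Returns a frame with columns
    model, n_components, auc, ci_low, ci_high, p, sens, spec, ppv.
    """
    df = cohort.df
    if "group" not in df.columns:
        raise ValueError("cohort is not labelled; run label_pre_ra first")
    mask = df["group"].isin(["pre-RA", "arthralgia"]).to_numpy()
    sub = df[mask].reset_index(drop=True)
    values = component_matrix(sub, subset_completions(completions, mask))
    outcome = (sub["group"] == "pre-RA").to_numpy()

    rows = []
    for label, extra in enrichments:
        comps = base.components + tuple(extra)
        model = CompositeModel(comps, name=label if label else "+".join(comps))
        scores = composite_score(values, model)
        curve = roc(scores, outcome)
        m = metrics_at_cut(scores, outcome, cut, ci_method=ci_method)
        rows.append(
            {
                "model": model.name,
                "n_components": len(model),
                "auc": curve.auc,
                "ci_low": curve.auc_ci[0],
                "ci_high": curve.auc_ci[1],
                "p": curve.auc_p,
                "sens": 100 * m.sensitivity,
                "spec": 100 * m.specificity,
                "ppv": 100 * m.ppv,
            }
        )
    return pd.DataFrame(rows)
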