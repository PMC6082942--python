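"""Cohort data model for first-visit rheumatology patients.

The package analyses a prospective first-visit cohort in which every patient
carries 13 ternary joint-symptom items, a four-marker serology panel
(rheumatoid factor, ACPA, C-reactive protein, serum survivin), a first-visit
joint examination, and a longitudinal outcome (months to rheumatoid arthritis
or censoring within a 48-month horizon).  This module defines the record and
cohort containers, dichotomises raw serology at the clinical cut-offs,
computes the EULAR/ACR 2010 classification score, assigns the first-visit
class (RA / undifferentiated arthritis / arthralgia), and partitions the
arthralgia group into pre-RA (progressed during follow-up) and remaining
arthralgia.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per patient (see :data:`COHORT_COLUMNS`); :class:`PatientRecord` offers a
typed scalar view of a single row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "N_SYMPTOMS",
    "HORIZON_MONTHS",
    "SYMPTOM_LABELS",
    "SYMPTOM_COLUMNS",
    "MARKER_COLUMNS",
    "COHORT_COLUMNS",
    "InputError",
    "SerologyCutoffs",
    "SerologyPanel",
    "BinaryMarkers",
    "JointExam",
    "PatientRecord",
    "Cohort",
    "dichotomize",
    "add_binary_markers",
    "eular_acr_2010_score",
    "eular_scores",
    "classify_first_visit",
    "assign_first_visit_classes",
    "label_pre_ra",
]

N_SYMPTOMS = 13
HORIZON_MONTHS = 48

#: The 13 first-visit joint-symptom items, in their fixed 1-based order.
SYMPTOM_LABELS = (
    "joint symptoms onset <1 year",
    "4-10 joints with symptoms",
    "symptoms located in MCP joints",
    "symptoms located in MTP joints",
    "symptoms in several small joint regions",
    "symmetric symptoms and signs",
    "morning stiffness >=60 min",
    "most severe symptoms in early morning",
    "improvement of symptoms during the day",
    "increasing number of joints with symptoms over time",
    "patient experience of swollen small hand joints",
    "first-degree relative with RA",
    "local tenderness of involved joints at examination",
)

SYMPTOM_COLUMNS = tuple(f"s{i}" for i in range(1, N_SYMPTOMS + 1))
MARKER_COLUMNS = (
    "rf_pos",
    "acpa_pos",
    "any_ab",
    "crp_high",
    "survivin_pos",
    "female_over_50",
)

#: Cohort CSV / DataFrame schema, one row per patient.
COHORT_COLUMNS = (
    ("id", "age", "sex", "smoker")
    + SYMPTOM_COLUMNS
    + (
        "rf_uml",
        "acpa_auml",
        "crp_mgl",
        "survivin_pgml",
        "n_large",
        "n_small",
        "swelling",
        "duration_wk",
        "months_to_ra",
        "event_ra",
    )
)


class InputError(ValueError):
    """Raised when a record field is invalid; the message names the field."""


def _check_nonneg_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise InputError(f"{name} must be non-negative and finite, got {value!r}")
    return value


@dataclass(frozen=True)
class SerologyCutoffs:
    """Clinical positivity cut-offs for the serology panel.

    RF, CRP and survivin are positive at >= their cut-off; ACPA is positive
    strictly above its cut-off (20 AU/ml corresponds to mean+2SD of healthy
    controls, values *above* it are regarded positive).  ``high_mult`` defines
    "high-positive" antibody levels (> 3x cut-off) for the EULAR/ACR 2010
    serology category.
    """

    rf_cut: float = 20.0  # U/ml
    acpa_cut: float = 20.0  # AU/ml
    crp_cut: float = 5.0  # mg/L
    survivin_cut: float = 450.0  # pg/ml
    high_mult: float = 3.0

    def __post_init__(self) -> None:
        for name in ("rf_cut", "acpa_cut", "crp_cut", "survivin_cut"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be strictly positive")
        if self.high_mult <= 1:
            raise InputError("high_mult must exceed 1")


@dataclass(frozen=True)
class SerologyPanel:
    """Raw serology values; below-detection measurements are stored as 0."""

    rf: float  # U/ml
    acpa: float  # AU/ml
    crp: float  # mg/L
    survivin: float  # pg/ml

    def __post_init__(self) -> None:
        for name in ("rf", "acpa", "crp", "survivin"):
            object.__setattr__(self, name, _check_nonneg_finite(name, getattr(self, name)))


@dataclass(frozen=True)
class BinaryMarkers:
    rf_pos: bool
    acpa_pos: bool
    any_ab: bool
    crp_high: bool
    survivin_pos: bool
    female_over_50: bool

    def __post_init__(self) -> None:
        if self.any_ab != (self.rf_pos or self.acpa_pos):
            raise InputError("any_ab must equal rf_pos OR acpa_pos")


@dataclass(frozen=True)
class JointExam:
    """First-visit joint examination summary for the 2010 criteria form."""

    n_large_involved: int
    n_small_involved: int
    swelling_present: bool
    duration_weeks: float

    def __post_init__(self) -> None:
        for name in ("n_large_involved", "n_small_involved"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InputError(f"{name} must be a non-negative integer, got {v!r}")
        _check_nonneg_finite("duration_weeks", self.duration_weeks)


@dataclass
class PatientRecord:
    """One first-visit patient.

    ``symptoms`` is the 13-slot ternary vector (True / False / None for
    missing) in the fixed item order of :data:`SYMPTOM_LABELS`.
    ``first_visit_class`` is assigned by :func:`classify_first_visit`, never
    supplied as input.
    """

    id: str
    age: float
    sex: str  # "female" | "male"
    smoker: bool
    symptoms: list = field(default_factory=lambda: [None] * N_SYMPTOMS)
    serology: SerologyPanel = None
    exam: JointExam = None
    months_to_ra: Optional[float] = None
    event_ra: bool = False
    first_visit_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise InputError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if len(self.symptoms) != N_SYMPTOMS:
            raise InputError(f"symptoms must have exactly {N_SYMPTOMS} slots")
        if self.event_ra and self.months_to_ra is None:
            raise InputError("event_ra implies months_to_ra present")
        if self.months_to_ra is not None and not (0 <= self.months_to_ra <= HORIZON_MONTHS):
            raise InputError("months_to_ra must lie in [0, 48]")


def dichotomize(
    panel: SerologyPanel,
    age: float,
    sex: str,
    cutoffs: SerologyCutoffs = SerologyCutoffs(),
) -> BinaryMarkers:
    """Dichotomise raw serology and demographics into the six binary markers.

    RF, CRP and survivin flags use >= their cut-off; ACPA uses strict >.
    ``female_over_50`` is the single conjunctive flag female AND age > 50
    (exactly 50 is excluded).  The operation is idempotent and field-order
    invariant by construction.
    """
    rf_pos = panel.rf >= cutoffs.rf_cut
    acpa_pos = panel.acpa > cutoffs.acpa_cut
    return BinaryMarkers(
        rf_pos=rf_pos,
        acpa_pos=acpa_pos,
        any_ab=rf_pos or acpa_pos,
        crp_high=panel.crp >= cutoffs.crp_cut,
        survivin_pos=panel.survivin >= cutoffs.survivin_cut,
        female_over_50=(sex == "female") and (age > 50),
    )


def add_binary_markers(df: pd.DataFrame, cutoffs: SerologyCutoffs = SerologyCutoffs()) -> pd.DataFrame:
    """Vectorised :func:`dichotomize` over a cohort frame.

    Returns a copy with the six boolean marker columns appended.
    """
    for col in ("rf_uml", "acpa_auml", "crp_mgl", "survivin_pgml"):
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise InputError(f"{col} contains negative or non-finite values")
    out = df.copy()
    out["rf_pos"] = df["rf_uml"] >= cutoffs.rf_cut
    out["acpa_pos"] = df["acpa_auml"] > cutoffs.acpa_cut
    out["any_ab"] = out["rf_pos"] | out["acpa_pos"]
    out["crp_high"] = df["crp_mgl"] >= cutoffs.crp_cut
    out["survivin_pos"] = df["survivin_pgml"] >= cutoffs.survivin_cut
    out["female_over_50"] = (df["sex"] == "female") & (df["age"] > 50)
    return out


def _joint_points(n_large: int, n_small: int) -> int:
    total = n_large + n_small
    if total > 10 and n_small >= 1:
        return 5
    if 4 <= n_small:
        return 3
    if 1 <= n_small:
        return 2
    if n_large >= 2:
        return 1
    return 0


def eular_acr_2010_score(
    exam: JointExam,
    serology: SerologyPanel,
    cutoffs: SerologyCutoffs = SerologyCutoffs(),
) -> int:
    """Additive EULAR/ACR 2010 classification score in [0, 10].

    Joint category: 1 large joint 0; 2-10 large 1; 1-3 small 2; 4-10 small 3;
    >10 joints including at least one small 5.  Serology: seronegative 0;
    low-positive RF or ACPA 2; high-positive (>3x cut-off) 3.  Acute phase:
    abnormal CRP 1 (ESR is not modelled; CRP is the only acute-phase value in
    the data model).  Duration: symptoms >= 6 weeks 1.  A total of >= 6 with
    joint swelling classifies RA.
    """
    pts = _joint_points(int(exam.n_large_involved), int(exam.n_small_involved))

    rf_pos = serology.rf >= cutoffs.rf_cut
    acpa_pos = serology.acpa > cutoffs.acpa_cut
    high = (serology.rf > cutoffs.high_mult * cutoffs.rf_cut) or (
        serology.acpa > cutoffs.high_mult * cutoffs.acpa_cut
    )
    if high:
        pts += 3
    elif rf_pos or acpa_pos:
        pts += 2

    if serology.crp >= cutoffs.crp_cut:
        pts += 1
    if exam.duration_weeks >= 6:
        pts += 1
    return pts


def eular_scores(df: pd.DataFrame, cutoffs: SerologyCutoffs = SerologyCutoffs()) -> np.ndarray:
    """Vectorised EULAR/ACR 2010 score over a cohort frame."""
    nl = df["n_large"].to_numpy(dtype=int)
    ns = df["n_small"].to_numpy(dtype=int)
    total = nl + ns
    joint = np.zeros(len(df), dtype=int)
    joint[nl >= 2] = 1
    joint[ns >= 1] = 2
    joint[ns >= 4] = 3
    joint[(total > 10) & (ns >= 1)] = 5

    rf = df["rf_uml"].to_numpy(dtype=float)
    acpa = df["acpa_auml"].to_numpy(dtype=float)
    low = (rf >= cutoffs.rf_cut) | (acpa > cutoffs.acpa_cut)
    high = (rf > cutoffs.high_mult * cutoffs.rf_cut) | (acpa > cutoffs.high_mult * cutoffs.acpa_cut)
    sero = np.where(high, 3, np.where(low, 2, 0))

    acute = (df["crp_mgl"].to_numpy(dtype=float) >= cutoffs.crp_cut).astype(int)
    duration = (df["duration_wk"].to_numpy(dtype=float) >= 6).astype(int)
    return joint + sero + acute + duration


def classify_first_visit(record: PatientRecord, cutoffs: SerologyCutoffs = SerologyCutoffs()) -> str:
    """First-visit class: joint swelling with score >= 6 is RA, swelling with
    score < 6 is undifferentiated arthritis (UA), no swelling is arthralgia."""
    if record.exam is None or record.serology is None:
        raise InputError("exam and serology must be present for classification")
    if not record.exam.swelling_present:
        cls = "arthralgia"
    elif eular_acr_2010_score(record.exam, record.serology, cutoffs) >= 6:
        cls = "RA"
    else:
        cls = "UA"
    record.first_visit_class = cls
    return cls


def assign_first_visit_classes(df: pd.DataFrame, cutoffs: SerologyCutoffs = SerologyCutoffs()) -> pd.DataFrame:
    """Vectorised first-visit classification; appends ``first_visit_class``."""
    scores = eular_scores(df, cutoffs)
    swelling = df["swelling"].to_numpy(dtype=bool)
    cls = np.where(~swelling, "arthralgia", np.where(scores >= 6, "RA", "UA"))
    out = df.copy()
    out["eular_score"] = scores
    out["first_visit_class"] = cls
    return out


@dataclass
class Cohort:
    """A first-visit cohort: one DataFrame row per patient.

    ``df`` follows :data:`COHORT_COLUMNS`; labelling operations append
    ``first_visit_class`` and ``group`` columns.  Patient ids must be unique.
    """

    df: pd.DataFrame
    horizon_months: int = HORIZON_MONTHS

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.df.columns]
        if missing:
            raise InputError(f"cohort frame lacks columns: {missing}")
        if self.df["id"].duplicated().any():
            raise InputError("patient ids must be unique")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_csv(cls, path, na_token: str = "NA") -> "Cohort":
        df = pd.read_csv(
            path,
            comment="#",
            na_values=[na_token],
            keep_default_na=False,
            dtype={"id": str, "sex": str},
        )
        return cls(df)

    def to_csv(self, path, na_token: str = "NA", header_lines: Optional[list] = None) -> None:
        with open(path, "w", newline="") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.df.to_csv(fh, index=False, na_rep=na_token)

    def symptom_matrix(self) -> np.ndarray:
        """n x 13 float matrix, 1/0 with NaN for missing items."""
        return self.df[list(SYMPTOM_COLUMNS)].to_numpy(dtype=float)

    def group_counts(self) -> pd.Series:
        if "group" not in self.df.columns:
            raise InputError("cohort is not yet labelled; run label_pre_ra first")
        return self.df["group"].value_counts()


def label_pre_ra(cohort: Cohort, cutoffs: SerologyCutoffs = SerologyCutoffs()) -> Cohort:
    """Assign first-visit classes and split arthralgia into pre-RA vs remaining.

    A first-visit arthralgia patient is pre-RA iff they developed RA
    (``event_ra``) within the follow-up horizon.  Records with a missing
    outcome are treated as censored at the horizon.  Returns a new cohort
    whose frame carries ``first_visit_class`` and ``group`` in
    {"arthralgia", "pre-RA", "UA", "RA"}; the pre-RA and remaining-arthralgia
    counts always sum to the arthralgia count.
    """
    df = assign_first_visit_classes(cohort.df, cutoffs)
    event = df["event_ra"].fillna(0).to_numpy(dtype=bool)
    months = df["months_to_ra"].to_numpy(dtype=float)
    progressed = event & (months <= cohort.horizon_months)
    group = df["first_visit_class"].to_numpy(dtype=object).copy()
    group[(group == "arthralgia") & progressed] = "pre-RA"
    df["group"] = group
    return Cohort(df, cohort.horizon_months)
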