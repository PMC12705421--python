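"""Patient-level data model, adjudication merging and cohort construction.

The canonical in-memory container is a :class:`pandas.DataFrame` with one
row per enrolled patient and the column schema in :data:`PATIENT_COLUMNS`.
Absent values (day-of-onset fields, laboratory values) are pandas NA.
:class:`PatientRecord` is the single-row dataclass view used for scalar
operations and validation messages.

Reference-standard construction
-------------------------------
Each patient carries two four-level adjudications (bacterial and viral):
Yes / Probable / Unlikely / No, produced by two independent reviewers with
an expert tie-break (:func:`merge_adjudications`).  Two inclusion rules
turn these into binary truth labels:

* ``consensus`` — only patients with a certain (Yes or No) adjudication on
  the relevant axis are kept; Yes is positive.
* ``forced`` — all patients are kept; Yes and Probable are positive,
  No and Unlikely negative.

Severity endpoints
------------------
"ICU-level care" is the receipt of acute mechanical ventilation,
vasopressor support and/or new renal replacement therapy within 7 days of
presentation (day 0 = presentation, day ≤ 7 inclusive).  ICU admission by
itself does not qualify.  The composite endpoint adds 28-day mortality.
Patients whose follow-up is shorter than the horizon and who have no
qualifying event are not evaluable and are dropped (with a logged count)
when a severity cohort is built.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ADJUDICATION_LEVELS = ("Yes", "Probable", "Unlikely", "No")

ENDPOINT_KINDS = ("bacterial", "viral", "severity", "severity_or_death")
INCLUSION_RULES = ("consensus", "forced")

#: Patient CSV column order; one row per patient, empty cells for absent.
PATIENT_COLUMNS = (
    "patient_id",
    "bacterial_score",
    "viral_score",
    "severity_score",
    "final_bacterial",
    "final_viral",
    "mech_vent_day",
    "vasopressor_day",
    "rrt_day",
    "icu_admit_day",
    "death_day",
    "qsofa",
    "delta_sofa",
    "lactate",
    "crp",
    "pct",
    "wbc",
    "antibiotics_day0",
    "immunosuppressed",
    "race",
    "site_id",
    "followup_day",
)

_DAY_COLUMNS = (
    "mech_vent_day",
    "vasopressor_day",
    "rrt_day",
    "icu_admit_day",
    "death_day",
)
_SEVERITY_COMPONENT_DAYS = ("mech_vent_day", "vasopressor_day", "rrt_day")
_LAB_COLUMNS = ("lactate", "crp", "pct", "wbc")


class UnresolvedAdjudicationError(ValueError):
    """Two reviewers disagreed and no expert tie-break was supplied."""


@dataclasses.dataclass(frozen=True)
class AdjudicationCall:
    """One reviewer's call on both infection axes."""

    reviewer_id: str
    bacterial: str
    viral: str

    def __post_init__(self):
        for axis in ("bacterial", "viral"):
            level = getattr(self, axis)
            if level not in ADJUDICATION_LEVELS:
                raise ValueError(
                    f"{axis} adjudication must be one of "
                    f"{ADJUDICATION_LEVELS}, got {level!r}"
                )


@dataclasses.dataclass
class PatientRecord:
    """One enrolled patient; ``None`` encodes an absent value."""

    patient_id: str
    bacterial_score: int
    viral_score: int
    severity_score: int
    final_bacterial: str
    final_viral: str
    mech_vent_day: Optional[int] = None
    vasopressor_day: Optional[int] = None
    rrt_day: Optional[int] = None
    icu_admit_day: Optional[int] = None
    death_day: Optional[int] = None
    qsofa: int = 0
    delta_sofa: Optional[int] = None
    lactate: Optional[float] = None
    crp: Optional[float] = None
    pct: Optional[float] = None
    wbc: Optional[float] = None
    antibiotics_day0: Optional[bool] = None
    immunosuppressed: bool = False
    race: str = "Unknown"
    site_id: str = "site-1"
    followup_day: int = 28

    def validate(self) -> "PatientRecord":
        for field in ("bacterial_score", "viral_score", "severity_score"):
            v = getattr(self, field)
            if int(v) != v or not 0 <= int(v) <= 50:
                raise ValueError(
                    f"{self.patient_id}: {field}={v!r} not an integer in [0, 50]"
                )
        for axis in ("final_bacterial", "final_viral"):
            if getattr(self, axis) not in ADJUDICATION_LEVELS:
                raise ValueError(
                    f"{self.patient_id}: {axis}={getattr(self, axis)!r} "
                    f"not in {ADJUDICATION_LEVELS}"
                )
        if self.qsofa not in (0, 1, 2, 3):
            raise ValueError(f"{self.patient_id}: qsofa={self.qsofa!r} not in 0–3")
        for field in _DAY_COLUMNS:
            day = getattr(self, field)
            if day is not None and not 0 <= day <= self.followup_day:
                raise ValueError(
                    f"{self.patient_id}: {field}={day} outside "
                    f"[0, followup_day={self.followup_day}]"
                )
        for field in _LAB_COLUMNS:
            v = getattr(self, field)
            if v is not None and v < 0:
                raise ValueError(f"{self.patient_id}: {field}={v} is negative")
        return self


@dataclasses.dataclass
class Cohort:
    """An analysis cohort: records, binary truth labels, provenance.

    ``data`` holds one row per included patient; ``y`` is the boolean
    endpoint label aligned with ``data``; ``excluded`` counts dropped
    records per reason.
    """

    data: pd.DataFrame
    endpoint_kind: str
    inclusion_rule: str
    y: np.ndarray
    excluded: Mapping[str, int] = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.data) - self.y.sum())

    def score_column(self, score_axis: Optional[str] = None) -> str:
        """Score column matching *score_axis* (default: the endpoint's own)."""
        axis = score_axis or self.endpoint_kind
        if axis in ("severity", "severity_or_death", "composite"):
            return "severity_score"
        if axis in ("bacterial", "viral"):
            return f"{axis}_score"
        raise ValueError(f"unknown score axis {axis!r}")


# ---------------------------------------------------------------------------
# Adjudication merging


def merge_adjudications(
    call1: AdjudicationCall,
    call2: AdjudicationCall,
    expert: Optional[AdjudicationCall] = None,
) -> tuple[str, str]:
    """Merge two reviewers' calls (plus expert tie-break) into final labels.

    Returns ``(final_bacterial, final_viral)``.  On each axis the two
    reviewers' concordant call stands; a discordant axis takes the expert's
    call.  A discordant axis without an expert raises
    :class:`UnresolvedAdjudicationError`; an expert supplied when both axes
    are concordant is ignored with a warning.
    """
    discordant = [
        axis
        for axis in ("bacterial", "viral")
        if getattr(call1, axis) != getattr(call2, axis)
    ]
    if discordant and expert is None:
        raise UnresolvedAdjudicationError(
            f"unresolved adjudication on axis(es) {discordant}: "
            f"{call1.reviewer_id}≠{call2.reviewer_id} with no expert call"
        )
    if not discordant and expert is not None:
        warnings.warn(
            "expert call supplied for fully concordant reviews; ignored",
            stacklevel=2,
        )
    final = {}
    for axis in ("bacterial", "viral"):
        if getattr(call1, axis) == getattr(call2, axis):
            final[axis] = getattr(call1, axis)
        else:
            final[axis] = getattr(expert, axis)
    return final["bacterial"], final["viral"]


# ---------------------------------------------------------------------------
# Endpoint derivation


def derive_severity_endpoint(record, horizon_days: int = 7) -> bool:
    """True iff any ICU-level-care component occurred within the horizon.

    Components are mechanical ventilation, vasopressor use and new renal
    replacement therapy; "within 7 days" is day ≤ 7 inclusive.  ICU
    admission alone does not qualify.  Accepts a :class:`PatientRecord` or
    a mapping/Series with the component day fields.
    """
    if horizon_days < 0:
        raise ValueError(f"horizon_days must be ≥ 0, got {horizon_days}")
    for field in _SEVERITY_COMPONENT_DAYS:
        day = _get(record, field)
        if day is not None and day <= horizon_days:
            return True
    return False


def derive_composite_endpoint(record, horizon_days: int = 7) -> bool:
    """Severity endpoint OR death within 28 days."""
    if derive_severity_endpoint(record, horizon_days):
        return True
    death = _get(record, "death_day")
    return death is not None and death <= 28


def _get(record, field):
    v = getattr(record, field, None) if not isinstance(record, Mapping) else record.get(field)
    if isinstance(record, pd.Series):
        v = record.get(field)
    if v is None or (v is pd.NA) or (isinstance(v, float) and np.isnan(v)):
        return None
    return int(v)


def severity_endpoint_flags(df: pd.DataFrame, horizon_days: int = 7) -> pd.Series:
    """Vectorised ICU-level-care endpoint over a patient DataFrame."""
    if horizon_days < 0:
        raise ValueError(f"horizon_days must be ≥ 0, got {horizon_days}")
    flag = pd.Series(False, index=df.index)
    for field in _SEVERITY_COMPONENT_DAYS:
        days = pd.to_numeric(df[field], errors="coerce")
        flag |= days.le(horizon_days).fillna(False)
    return flag


def composite_endpoint_flags(df: pd.DataFrame, horizon_days: int = 7) -> pd.Series:
    death = pd.to_numeric(df["death_day"], errors="coerce")
    return severity_endpoint_flags(df, horizon_days) | death.le(28).fillna(False)


# ---------------------------------------------------------------------------
# Cohort construction


def build_cohort(
    records: pd.DataFrame,
    endpoint_kind: str,
    inclusion_rule: str = "consensus",
    horizon_days: int = 7,
) -> Cohort:
    """Build an analysis cohort with binary truth labels.

    For the diagnostic endpoints (``bacterial``, ``viral``) the inclusion
    rule selects consensus (certain Yes/No only) or forced (everyone, with
    Probable→positive, Unlikely→negative) labelling.  For the severity
    endpoints every record evaluable for the outcome window is kept
    regardless of adjudication; non-evaluable records (follow-up shorter
    than the horizon and no qualifying event) are dropped and counted in
    ``Cohort.excluded``.
    """
    if endpoint_kind not in ENDPOINT_KINDS:
        raise ValueError(
            f"endpoint_kind must be one of {ENDPOINT_KINDS}, got {endpoint_kind!r}"
        )
    if inclusion_rule not in INCLUSION_RULES:
        raise ValueError(
            f"inclusion_rule must be one of {INCLUSION_RULES}, got {inclusion_rule!r}"
        )
    df = records.reset_index(drop=True)
    excluded: dict[str, int] = {}

    if endpoint_kind in ("bacterial", "viral"):
        labels = df[f"final_{endpoint_kind}"]
        bad = ~labels.isin(ADJUDICATION_LEVELS)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} records have unresolved {endpoint_kind} "
                "adjudications; run merge_adjudications first"
            )
        if inclusion_rule == "consensus":
            keep = labels.isin(["Yes", "No"])
            excluded["uncertain_adjudication"] = int((~keep).sum())
            df = df[keep].reset_index(drop=True)
            y = (df[f"final_{endpoint_kind}"] == "Yes").to_numpy()
        else:
            y = labels.isin(["Yes", "Probable"]).to_numpy()
    else:
        horizon = horizon_days if endpoint_kind == "severity" else 28
        if endpoint_kind == "severity":
            event = severity_endpoint_flags(df, horizon_days)
        else:
            event = composite_endpoint_flags(df, horizon_days)
        followup = pd.to_numeric(df["followup_day"], errors="coerce")
        evaluable = event | followup.ge(horizon).fillna(False)
        excluded["not_evaluable_for_outcome"] = int((~evaluable).sum())
        df = df[evaluable].reset_index(drop=True)
        y = event[evaluable.to_numpy()].to_numpy()

    if len(df) == 0:
        raise ValueError(
            f"empty cohort for endpoint={endpoint_kind!r}, rule={inclusion_rule!r}"
        )
    for reason, n in excluded.items():
        if n:
            logger.info(
                "build_cohort(%s, %s): excluded %d records (%s)",
                endpoint_kind, inclusion_rule, n, reason,
            )
    return Cohort(df, endpoint_kind, inclusion_rule, np.asarray(y, bool), excluded)


# ---------------------------------------------------------------------------
# Patient CSV dialect

_INT_NULLABLE = _DAY_COLUMNS + ("delta_sofa",)
_BOOL_COLUMNS = ("antibiotics_day0", "immunosuppressed")


def read_patient_csv(path) -> pd.DataFrame:
    """Read the Patient CSV dialect (header required, empty cells = absent)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "site_id": str, "race": str})
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient CSV missing columns: {missing}")
    df = df[list(PATIENT_COLUMNS)]
    for col in _INT_NULLABLE:
        df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
    for col in _BOOL_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
    for col in _LAB_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    for col in ("bacterial_score", "viral_score", "severity_score", "qsofa",
                "followup_day"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    validate_patients(df)
    return df


def write_patient_csv(df: pd.DataFrame, path) -> None:
    """Write the Patient CSV dialect (UTF-8, empty cells for absent)."""
    out = df[list(PATIENT_COLUMNS)].copy()
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False, lineterminator="\n")


def validate_patients(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a patient DataFrame; raises ``ValueError`` on the first defect."""
    for col in ("bacterial_score", "viral_score", "severity_score"):
        s = df[col]
        if ((s < 0) | (s > 50)).any():
            raise ValueError(f"{col} outside [0, 50]")
    if not df["qsofa"].isin([0, 1, 2, 3]).all():
        raise ValueError("qsofa outside {0,1,2,3}")
    for col in ("final_bacterial", "final_viral"):
        bad = ~df[col].isin(ADJUDICATION_LEVELS)
        if bad.any():
            raise ValueError(f"{col} has invalid levels: "
                             f"{sorted(df.loc[bad, col].unique())}")
    followup = pd.to_numeric(df["followup_day"], errors="coerce")
    for col in _DAY_COLUMNS:
        days = pd.to_numeric(df[col], errors="coerce")
        if (days < 0).any() or (days > followup).any():
            raise ValueError(f"{col} outside [0, followup_day]")
    for col in _LAB_COLUMNS:
        if (df[col].dropna() < 0).any():
            raise ValueError(f"{col} has negative values")
    return df


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Assemble validated :class:`PatientRecord` objects into a DataFrame."""
    rows = [dataclasses.asdict(r.validate()) for r in records]
    df = pd.DataFrame(rows, columns=list(PATIENT_COLUMNS))
    for col in _INT_NULLABLE:
        df[col] = df[col].astype("Int64")
    return df
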