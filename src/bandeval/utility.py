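"""Potential-clinical-utility analyses: antibiotics, sepsis surrogate, lactate.

Three preliminary, hypothesis-generating analyses that translate band
metrics into treatment-relevant counts:

* **Antibiotic reclassification** — among patients whose day-0 antibiotic
  treatment disagreed with the final adjudication, how many would the
  Bacterial band have flagged?  Undertreated (adjudicated bacterial, no
  day-0 antibiotics) count as flagged when the band is Moderate or higher;
  overtreated (non-bacterial, treated) when the band is Low or Very Low.

* **Bacterial-sepsis surrogate** — sepsis was not adjudicated, so
  "adjudicated bacterial infection AND (ΔSOFA ≥ 2 OR ICU-level care within
  7 days)" stands in for it; the 5×5 Bacterial × Severity band cross-tab
  shows where surrogate-positive patients concentrate.

* **Lactate zones** — patients with indeterminate lactate (2–4 mmol/l,
  closed interval) are the zone where lactate is uninformative; among
  those with a severe course (ICU-level care or 28-day death), the
  fraction with a Moderate-or-higher Severity band measures how much the
  score resolves lactate's gray zone.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bands import BANDS_ASCENDING, BANDS_DESCENDING, Band, assign_bands
from .cohort import (
    Cohort,
    composite_endpoint_flags,
    severity_endpoint_flags,
)

logger = logging.getLogger(__name__)

MODERATE_PLUS = (Band.MODERATE, Band.HIGH, Band.VERY_HIGH)
LOW_OR_VERY_LOW = (Band.VERY_LOW, Band.LOW)

#: Lactate zones in mmol/l: below 2, 2–4 inclusive (indeterminate), above 4.
DEFAULT_LACTATE_ZONES = (
    ("low", 0.0, 2.0),  # [0, 2)
    ("indeterminate", 2.0, 4.0),  # [2, 4]
    ("high", 4.0, float("inf")),  # (4, inf)
)


@dataclasses.dataclass(frozen=True)
class ReclassGroup:
    """One mistreated group with the count the band would have flagged."""

    n_total: int
    n_flagged: int

    @property
    def pct_flagged(self) -> float:
        return 100 * self.n_flagged / self.n_total if self.n_total else float("nan")


@dataclasses.dataclass(frozen=True)
class LactateZoneSummary:
    zone: str
    n: int
    n_severe: int
    n_severe_flagged: int  # severe with Severity band >= Moderate

    @property
    def pct_flagged(self) -> float:
        return (
            100 * self.n_severe_flagged / self.n_severe
            if self.n_severe
            else float("nan")
        )


def antibiotic_reclassification(
    cohort: Cohort,
    convention: str = "table",
) -> Dict[str, ReclassGroup]:
    """Undertreated/overtreated counts and band-flagged fractions.

    Uses consensus semantics on the bacterial axis: positives are final
    adjudication Yes, negatives No; Probable/Unlikely and records with a
    missing antibiotics flag are excluded (counted in the log).  Returns
    ``{"undertreated": ..., "overtreated": ...}``.
    """
    df = cohort.data
    abx = df["antibiotics_day0"]
    resolved = df["final_bacterial"].isin(["Yes", "No"]) & abx.notna()
    n_dropped = int((~resolved).sum())
    if n_dropped:
        logger.info(
            "antibiotic_reclassification: excluded %d records "
            "(unresolved adjudication or missing antibiotics flag)",
            n_dropped,
        )
    sub = df[resolved]
    bacterial = (sub["final_bacterial"] == "Yes").to_numpy()
    treated = sub["antibiotics_day0"].astype(int).to_numpy().astype(bool)
    band_idx = assign_bands(sub["bacterial_score"].to_numpy(), convention)

    under = bacterial & ~treated
    over = ~bacterial & treated
    flagged_under = under & (band_idx >= Band.MODERATE.value)
    flagged_over = over & (band_idx <= Band.LOW.value)
    return {
        "undertreated": ReclassGroup(int(under.sum()), int(flagged_under.sum())),
        "overtreated": ReclassGroup(int(over.sum()), int(flagged_over.sum())),
    }


def sepsis_surrogate(df: pd.DataFrame, horizon_days: int = 7) -> pd.Series:
    """Boolean (nullable) bacterial-sepsis surrogate per record.

    True iff adjudicated bacterial (Yes) AND (ΔSOFA ≥ 2 OR ICU-level care
    within the horizon).  Bacterial-negative records are False regardless
    of organ dysfunction.  A missing ΔSOFA with a negative severity
    endpoint leaves the record undetermined (pd.NA) — it is excluded from
    cross-tab denominators.
    """
    bacterial = df["final_bacterial"] == "Yes"
    severe = severity_endpoint_flags(df, horizon_days)
    delta = pd.to_numeric(df["delta_sofa"], errors="coerce")
    organ = delta.ge(2)
    out = pd.Series(pd.NA, index=df.index, dtype="boolean")
    out[~bacterial] = False
    out[bacterial & (severe | organ.fillna(False))] = True
    determined_neg = bacterial & ~severe & delta.notna() & ~organ.fillna(False)
    out[determined_neg] = False
    return out


def sepsis_crosstab(
    cohort: Cohort,
    convention: str = "table",
    horizon_days: int = 7,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """(percent, n) 5×5 tables of the sepsis surrogate.

    Rows are Bacterial bands, columns Severity bands, both ordered
    Very High → Very Low as printed.  Cells with no determined patients
    hold NaN percent and n = 0.
    """
    df = cohort.data
    surrogate = sepsis_surrogate(df, horizon_days)
    determined = surrogate.notna()
    bac_idx = assign_bands(df["bacterial_score"].to_numpy(), convention)
    sev_idx = assign_bands(df["severity_score"].to_numpy(), convention)
    labels = [str(b) for b in BANDS_DESCENDING]
    pct = pd.DataFrame(np.nan, index=labels, columns=labels)
    n = pd.DataFrame(0, index=labels, columns=labels)
    pct.index.name = n.index.name = "bacterial_band"
    pct.columns.name = n.columns.name = "severity_band"
    for bb in BANDS_DESCENDING:
        for sb in BANDS_DESCENDING:
            cell = determined & (bac_idx == bb.value) & (sev_idx == sb.value)
            total = int(cell.sum())
            n.loc[str(bb), str(sb)] = total
            if total:
                hits = int((surrogate[cell] == True).sum())  # noqa: E712
                pct.loc[str(bb), str(sb)] = 100 * hits / total
    return pct, n


def lactate_zone_analysis(
    cohort: Cohort,
    zones: Sequence[Tuple[str, float, float]] = DEFAULT_LACTATE_ZONES,
    convention: str = "table",
    horizon_days: int = 7,
) -> Dict[str, LactateZoneSummary]:
    """Severe-course counts and Moderate+ flags per lactate zone.

    A severe course is ICU-level care within the horizon or death within
    28 days.  Zone boundaries: the first zone is [lo, hi), the middle
    zones close both ends ([2, 4] for the indeterminate zone), the last is
    (lo, inf).  Records without a lactate value are excluded.
    """
    df = cohort.data
    lactate = pd.to_numeric(df["lactate"], errors="coerce")
    if (lactate.dropna() < 0).any():
        raise ValueError("negative lactate values")
    severe = composite_endpoint_flags(df, horizon_days).to_numpy()
    band_idx = assign_bands(df["severity_score"].to_numpy(), convention)
    flagged = band_idx >= Band.MODERATE.value
    out: Dict[str, LactateZoneSummary] = {}
    for i, (name, lo, hi) in enumerate(zones):
        vals = lactate.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if i == 0:
                sel = (vals >= lo) & (vals < hi)
            elif np.isinf(hi):
                sel = vals > lo
            else:
                sel = (vals >= lo) & (vals <= hi)
        sel &= ~np.isnan(vals)
        out[name] = LactateZoneSummary(
            zone=name,
            n=int(sel.sum()),
            n_severe=int((sel & severe).sum()),
            n_severe_flagged=int((sel & severe & flagged).sum()),
        )
    return out
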