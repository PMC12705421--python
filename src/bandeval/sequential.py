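"""Sequential risk stratification: qSOFA strata refined by Severity bands.

qSOFA (quick Sequential Organ Failure Assessment, 0–3) dichotomises at ≥2
into low-risk (0–1) and high-risk (2–3) strata.  Within each stratum the
pre-test rate of the severity endpoint (ICU-level care within 7 days) is
refined by the five-band Severity score: the per-(stratum, band) event
rates quantify how much a band reclassifies risk beyond the bedside score
alone.

The combined rule flags a patient when qSOFA ≥ 2 *or* the Severity band
reaches a configurable cutoff; since its positives are a superset of the
qSOFA-alone positives, combined sensitivity can only rise (at the price of
specificity).  Differences in event rates between strata or bands are
tested with Fisher's exact test.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats

from .bands import BANDS_ASCENDING, Band, assign_bands
from .cohort import Cohort

QSOFA_HIGH_CUTOFF = 2  # qSOFA >= 2 is the high-risk stratum


@dataclasses.dataclass(frozen=True)
class BandRate:
    n: int
    n_events: int

    @property
    def rate(self) -> float:
        """Event rate in percent; NaN for an empty cell."""
        return 100 * self.n_events / self.n if self.n else float("nan")


@dataclasses.dataclass(frozen=True)
class StratifiedRates:
    """Outcome rates for one qSOFA stratum, overall and per Severity band."""

    stratum: str  # "qsofa_low" or "qsofa_high"
    n: int
    n_events: int
    per_band: Dict[Band, BandRate]

    @property
    def overall_rate(self) -> float:
        return 100 * self.n_events / self.n if self.n else float("nan")


def stratified_outcome_rates(
    cohort: Cohort,
    convention: str = "table",
) -> Dict[str, StratifiedRates]:
    """Pre- and post-stratification event rates per qSOFA stratum.

    The cohort must carry a severity-type endpoint (binary ``y``) and a
    qsofa column.  Empty strata are reported with NaN rates and a warning.
    """
    qsofa = cohort.data["qsofa"].to_numpy(int)
    band_idx = assign_bands(
        cohort.data[cohort.score_column("severity")].to_numpy(), convention
    )
    y = cohort.y
    out: Dict[str, StratifiedRates] = {}
    for name, sel in (
        ("qsofa_low", qsofa < QSOFA_HIGH_CUTOFF),
        ("qsofa_high", qsofa >= QSOFA_HIGH_CUTOFF),
    ):
        if not sel.any():
            warnings.warn(f"stratum {name!r} is empty", stacklevel=2)
            out[name] = StratifiedRates(name, 0, 0, {
                b: BandRate(0, 0) for b in BANDS_ASCENDING
            })
            continue
        per_band = {}
        for band in BANDS_ASCENDING:
            cell = sel & (band_idx == band.value)
            per_band[band] = BandRate(int(cell.sum()), int((cell & y).sum()))
        out[name] = StratifiedRates(
            name, int(sel.sum()), int((sel & y).sum()), per_band
        )
    return out


def combined_rule_sensitivity(
    cohort: Cohort,
    band_cutoff: Band = Band.MODERATE,
    convention: str = "table",
) -> Tuple[float, float]:
    """Sensitivity (%) of qSOFA alone versus qSOFA OR Severity band.

    qSOFA-alone positive: qSOFA ≥ 2.  Combined positive: qSOFA ≥ 2 or the
    Severity band at/above *band_cutoff* (default Moderate — an analysis
    parameter, not an established clinical rule).  Sensitivities are taken
    over endpoint-positive patients; raises if there are none.
    """
    y = cohort.y
    if not y.any():
        raise ValueError("no endpoint-positive patients; sensitivity undefined")
    qsofa_pos = cohort.data["qsofa"].to_numpy(int) >= QSOFA_HIGH_CUTOFF
    band_idx = assign_bands(
        cohort.data[cohort.score_column("severity")].to_numpy(), convention
    )
    combined_pos = qsofa_pos | (band_idx >= band_cutoff.value)
    n_pos = int(y.sum())
    sens_alone = 100 * int((qsofa_pos & y).sum()) / n_pos
    sens_combined = 100 * int((combined_pos & y).sum()) / n_pos
    return sens_alone, sens_combined


def combined_rule_specificity(
    cohort: Cohort,
    band_cutoff: Band = Band.MODERATE,
    convention: str = "table",
) -> Tuple[float, float]:
    """Specificity (%) of qSOFA alone versus the combined rule."""
    y = cohort.y
    if y.all():
        raise ValueError("no endpoint-negative patients; specificity undefined")
    qsofa_pos = cohort.data["qsofa"].to_numpy(int) >= QSOFA_HIGH_CUTOFF
    band_idx = assign_bands(
        cohort.data[cohort.score_column("severity")].to_numpy(), convention
    )
    combined_pos = qsofa_pos | (band_idx >= band_cutoff.value)
    n_neg = int((~y).sum())
    spec_alone = 100 * int((~qsofa_pos & ~y).sum()) / n_neg
    spec_combined = 100 * int((~combined_pos & ~y).sum()) / n_neg
    return spec_alone, spec_combined


def fisher_exact(table, alternative: str = "two-sided") -> float:
    """Two-sided Fisher's exact p-value for a 2×2 count table.

    The two-sided p sums hypergeometric probabilities of all tables (at
    the observed margins) no more probable than the observed one.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2×2 table, got shape {arr.shape}")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        if (arr < 0).any() or (arr != np.floor(arr)).any():
            raise ValueError("table entries must be non-negative integers")
        arr = arr.astype(int)
    return float(stats.fisher_exact(arr, alternative=alternative).pvalue)
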