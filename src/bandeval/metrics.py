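"""Band-stratified accuracy metrics for five-band triage scores.

The evaluation object is the 5×2 band-by-truth contingency table
(:class:`BandTable`): for band *i*, ``a_i`` positives and ``b_i`` negatives
out of ``P`` total positives and ``N`` total negatives.

Stratum-specific likelihood ratio
---------------------------------
``LR_i = (a_i / P) / (b_i / N)`` — the ratio of the probabilities of the
result falling in band *i* among disease-positives versus negatives.  A
well-behaved five-band test shows LRs increasing monotonically from the
lowest to the highest band.

Rule-in / rule-out convention
-----------------------------
Per-band sensitivity and specificity are reported under the band's
clinical role.  Rule-in bands (High, Very High — and Moderate, which uses
the same formulas but is not actionable) treat a result in the band as a
test-positive::

    sens = a_i / P          spec = 1 − b_i / N

Rule-out bands (Low, Very Low) treat a result in the band as a
test-negative (a positive in the band is a false negative)::

    sens = 1 − a_i / P      spec = b_i / N

Under the rule-in formulas ``LR_i = sens_i / (1 − spec_i)`` exactly.

All metric functions keep exact rational arithmetic internally
(``fractions.Fraction``) and convert to float only at the reporting
surface; report rounding is half-up (1 d.p. for percentages, 2 d.p. for
likelihood ratios).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .bands import (
    ACTIONABLE_BANDS,
    BANDS_ASCENDING,
    BANDS_DESCENDING,
    Band,
    assign_bands,
)
from .cohort import Cohort

DEFAULT_CI_LEVEL = 0.80

#: Default clinical role per band.
BAND_ROLES: Dict[Band, str] = {
    Band.VERY_HIGH: "rule_in",
    Band.HIGH: "rule_in",
    Band.MODERATE: "neutral",  # rule-in-style formulas, not actionable
    Band.LOW: "rule_out",
    Band.VERY_LOW: "rule_out",
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at *ndigits* decimals (report convention)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclasses.dataclass(frozen=True)
class BandTable:
    """5×2 band-by-truth contingency with totals.

    ``counts[band] = (a, b)`` — positives and negatives whose score falls
    in *band*.
    """

    counts: Dict[Band, Tuple[int, int]]

    def __post_init__(self):
        for band in BANDS_ASCENDING:
            a, b = self.counts.get(band, (0, 0))
            if a < 0 or b < 0 or int(a) != a or int(b) != b:
                raise ValueError(f"{band}: counts must be non-negative integers")

    @property
    def n_positive(self) -> int:
        return sum(a for a, _ in self.counts.values())

    @property
    def n_negative(self) -> int:
        return sum(b for _, b in self.counts.values())

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative

    def cell(self, band: Band) -> Tuple[int, int]:
        return self.counts.get(band, (0, 0))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"band": str(b), "n_positive": self.cell(b)[0],
             "n_negative": self.cell(b)[1]}
            for b in BANDS_DESCENDING
        ]
        return pd.DataFrame(rows)


def build_band_contingency(
    cohort: Cohort,
    score_axis: Optional[str] = None,
    convention: str = "table",
) -> BandTable:
    """Cross-tabulate a cohort's bands against its binary truth labels."""
    if len(cohort) == 0:
        raise ValueError("cannot tabulate an empty cohort")
    col = cohort.score_column(score_axis)
    band_idx = assign_bands(cohort.data[col].to_numpy(), convention)
    y = cohort.y
    counts = {}
    for band in BANDS_ASCENDING:
        in_band = band_idx == band.value
        counts[band] = (int((in_band & y).sum()), int((in_band & ~y).sum()))
    return BandTable(counts)


# ---------------------------------------------------------------------------
# Per-band metrics (exact Fractions internally)


def _check_totals(table: BandTable):
    if table.n_positive == 0 or table.n_negative == 0:
        raise ValueError(
            "band metrics need both classes present "
            f"(P={table.n_positive}, N={table.n_negative})"
        )


def band_likelihood_ratio(table: BandTable, band: Band, exact: bool = False):
    """Stratum-specific likelihood ratio ``(a/P) / (b/N)`` of *band*.

    Returns ``inf`` when ``b == 0 < a`` and ``nan`` (undefined) when the
    band is empty in both classes.  With ``exact=True`` returns a
    :class:`fractions.Fraction` where finite.
    """
    _check_totals(table)
    a, b = table.cell(band)
    if a == 0 and b == 0:
        return float("nan")
    if b == 0:
        return math.inf
    lr = Fraction(a, table.n_positive) / Fraction(b, table.n_negative)
    return lr if exact else float(lr)


def band_rule_metrics(
    table: BandTable,
    band: Band,
    band_role: Optional[str] = None,
    exact: bool = False,
) -> Tuple[float, float]:
    """(sensitivity %, specificity %) of *band* under its clinical role.

    ``band_role`` is ``rule_in``, ``rule_out`` or ``neutral`` (same
    formulas as rule-in); defaults to the band's conventional role.
    """
    _check_totals(table)
    role = band_role or BAND_ROLES[band]
    if role not in ("rule_in", "rule_out", "neutral"):
        raise ValueError(f"unknown band role {band_role!r}")
    a, b = table.cell(band)
    P, N = table.n_positive, table.n_negative
    if role in ("rule_in", "neutral"):
        sens = 100 * Fraction(a, P)
        spec = 100 * (1 - Fraction(b, N))
    else:
        sens = 100 * (1 - Fraction(a, P))
        spec = 100 * Fraction(b, N)
    if exact:
        return sens, spec
    return float(sens), float(spec)


def band_probability(table: BandTable, band: Band, exact: bool = False):
    """Percent truly positive among patients whose result falls in *band*.

    This is the band's predictive value at the cohort prevalence.  An
    empty band returns ``nan`` (absent), never 0.
    """
    a, b = table.cell(band)
    if a + b == 0:
        return float("nan")
    p = 100 * Fraction(a, a + b)
    return p if exact else float(p)


def relative_frequency(table: BandTable, band: Band, exact: bool = False):
    """Percent of the whole cohort whose result falls in *band*."""
    if table.total == 0:
        raise ValueError("empty table")
    a, b = table.cell(band)
    f = 100 * Fraction(a + b, table.total)
    return f if exact else float(f)


# ---------------------------------------------------------------------------
# Likelihood-ratio confidence intervals


def lr_confidence_interval(
    table: BandTable,
    band: Band,
    level: float = DEFAULT_CI_LEVEL,
    method: str = "log_normal",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """Confidence interval for the band likelihood ratio.

    ``log_normal`` uses the delta-method interval on the log scale::

        exp( ln LR ± z · sqrt(1/a − 1/P + 1/b − 1/N) )

    with ``z`` the standard-normal quantile at ``(1 + level) / 2``.
    ``bootstrap`` resamples band assignments within each class
    (multinomial) and takes the percentile interval; it tolerates zero
    cells (a resample with an empty-band denominator contributes ``inf``).
    """
    _check_totals(table)
    if not 0 < level < 1:
        raise ValueError(f"CI level must be in (0, 1), got {level}")
    a, b = table.cell(band)
    P, N = table.n_positive, table.n_negative
    if method == "log_normal":
        if a == 0 or b == 0:
            raise ValueError(
                "log-normal LR interval undefined with a zero cell; "
                "use method='bootstrap'"
            )
        z = stats.norm.ppf(0.5 + level / 2)
        log_lr = math.log((a / P) / (b / N))
        se = math.sqrt(1 / a - 1 / P + 1 / b - 1 / N)
        return (math.exp(log_lr - z * se), math.exp(log_lr + z * se))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = rng.binomial(P, a / P, size=n_boot)
        neg = rng.binomial(N, b / N, size=n_boot)
        with np.errstate(divide="ignore", invalid="ignore"):
            lrs = (pos / P) / (neg / N)
        lrs = np.where((pos == 0) & (neg == 0), np.nan, lrs)
        lrs = lrs[~np.isnan(lrs)]
        lo, hi = np.quantile(lrs, [0.5 - level / 2, 0.5 + level / 2])
        return float(lo), float(hi)
    raise ValueError(f"unknown CI method {method!r}")


# ---------------------------------------------------------------------------
# Table-level summaries


def band_metrics_table(
    table: BandTable,
    level: float = DEFAULT_CI_LEVEL,
    ci_method: str = "log_normal",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Full per-band metrics table, rows ordered Very High → Very Low.

    Columns: band, role, n_positive, n_negative, sensitivity, specificity,
    lr, lr_ci_low, lr_ci_high, rel_freq, prob_in_band — all unrounded;
    report rounding belongs to the rendering layer.
    """
    rows = []
    for band in BANDS_DESCENDING:
        a, b = table.cell(band)
        sens, spec = band_rule_metrics(table, band)
        lr = band_likelihood_ratio(table, band)
        if a > 0 and b > 0 and ci_method == "log_normal":
            lo, hi = lr_confidence_interval(table, band, level, "log_normal")
        elif a + b > 0:
            lo, hi = lr_confidence_interval(
                table, band, level, "bootstrap", n_boot=n_boot, seed=seed
            )
        else:
            lo = hi = float("nan")
        rows.append(
            {
                "band": str(band),
                "role": BAND_ROLES[band],
                "n_positive": a,
                "n_negative": b,
                "sensitivity": sens,
                "specificity": spec,
                "lr": lr,
                "lr_ci_low": lo,
                "lr_ci_high": hi,
                "rel_freq": relative_frequency(table, band),
                "prob_in_band": band_probability(table, band),
            }
        )
    return pd.DataFrame(rows)


def lr_fold_range(lrs, reported_rounding: bool = True) -> float:
    """Fold range max(LR)/min(LR) across bands.

    *lrs* is a metrics DataFrame from :func:`band_metrics_table` or a
    sequence of per-band LRs.  By default the ratio is taken over the
    report-rounded (2 d.p.) values — the scale on which fold ranges are
    quoted clinically; ``reported_rounding=False`` uses exact values.
    Non-finite LRs are excluded with a warning.
    """
    if isinstance(lrs, pd.DataFrame):
        values = lrs["lr"].to_numpy(float)
    else:
        values = np.asarray(list(lrs), float)
    finite = np.isfinite(values)
    if not finite.all():
        warnings.warn("non-finite likelihood ratios excluded from fold range",
                      stacklevel=2)
        values = values[finite]
    if len(values) == 0 or (values <= 0).any():
        raise ValueError("fold range needs positive finite likelihood ratios")
    if reported_rounding:
        values = np.array([round_half_up(v, 2) for v in values])
    return float(values.max() / values.min())


def actionable_fraction(
    cohort: Cohort,
    axes=("bacterial",),
    convention: str = "table",
) -> Dict[str, float]:
    """Percent of patients in an actionable band, per axis and on ≥1 axis.

    Actionable bands are Very Low, Low, High and Very High (everything but
    Moderate).  Returns ``{axis: %, ..., "any": %}``.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    actionable_idx = {b.value for b in ACTIONABLE_BANDS}
    out: Dict[str, float] = {}
    any_mask = np.zeros(n, bool)
    for axis in axes:
        idx = assign_bands(
            cohort.data[cohort.score_column(axis)].to_numpy(), convention
        )
        mask = np.isin(idx, list(actionable_idx))
        out[axis] = float(100 * mask.sum() / n)
        any_mask |= mask
    out["any"] = float(100 * any_mask.sum() / n)
    return out
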