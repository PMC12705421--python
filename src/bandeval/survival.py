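"""Time-to-event analysis of ICU-level care by Severity band.

Events are the first ICU-level-care component (mechanical ventilation,
vasopressors, new renal replacement therapy) within the 0–7-day window;
patients without an event are administratively censored at day 7 (or at
their follow-up day if shorter).  Estimation is the Kaplan–Meier
product-limit curve, group comparison the log-rank test, and per-band
hazard ratios come from a Cox proportional-hazards fit with band
indicators against a reference band (Efron handling for tied event days).

Backed by lifelines (KaplanMeierFitter, multivariate_logrank_test,
CoxPHFitter).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .bands import BANDS_ASCENDING, Band, assign_bands
from .cohort import Cohort, _SEVERITY_COMPONENT_DAYS


@dataclasses.dataclass
class SurvivalCurve:
    """Product-limit estimate: step function of event-free probability."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step function with S(t) = 1 before the
        first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan–Meier estimate from event/censoring times and indicators."""
    t = np.asarray(times, float)
    e = np.asarray(events).astype(bool)
    if t.size == 0:
        raise ValueError("empty input")
    if (t < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    event_table = kmf.event_table
    observed = event_table[event_table["observed"] > 0]
    times_out = observed.index.to_numpy(float)
    surv = kmf.survival_function_at_times(times_out).to_numpy(float)
    at_risk = observed["at_risk"].to_numpy(int)
    return SurvivalCurve(
        times=times_out,
        survival=surv,
        at_risk=at_risk,
        n=len(t),
        n_events=int(e.sum()),
    )


def icu_care_survival_data(
    cohort_or_df,
    horizon_days: int = 7,
) -> Tuple[np.ndarray, np.ndarray]:
    """(time, event) pairs for the ICU-level-care process.

    Time is the earliest component day if any falls within the horizon
    (event = 1), else min(follow-up, horizon) (censored).
    """
    df = cohort_or_df.data if isinstance(cohort_or_df, Cohort) else cohort_or_df
    comp = np.full((len(df), len(_SEVERITY_COMPONENT_DAYS)), np.inf)
    for j, col in enumerate(_SEVERITY_COMPONENT_DAYS):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(float)
        comp[:, j] = np.where(np.isnan(vals), np.inf, vals)
    first = comp.min(axis=1)
    event = first <= horizon_days
    followup = pd.to_numeric(df["followup_day"], errors="coerce").to_numpy(float)
    censor_time = np.minimum(np.nan_to_num(followup, nan=horizon_days),
                             horizon_days)
    time = np.where(event, first, censor_time)
    return time, event


def logrank_test(groups: Sequence[Tuple[np.ndarray, np.ndarray]]):
    """Log-rank test across ≥2 groups of (times, events).

    Returns ``(chi2_statistic, p_value)``; requires at least one event
    overall.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times = np.concatenate([np.asarray(t, float) for t, _ in groups])
    events = np.concatenate([np.asarray(e).astype(bool) for _, e in groups])
    labels = np.concatenate(
        [np.full(len(t), i) for i, (t, _) in enumerate(groups)]
    )
    if not events.any():
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


def band_hazard_ratios(
    cohort: Cohort,
    reference: Band = Band.VERY_LOW,
    horizon_days: int = 7,
    convention: str = "table",
    ci_level: float = 0.80,
) -> pd.DataFrame:
    """Per-band hazard ratio of ICU-level care versus a reference band.

    Cox partial-likelihood point estimates over the 0–7-day window with
    band indicator covariates.  A zero-event band is reported with HR 0
    and a degenerate CI (it cannot enter the fit); a zero-event reference
    band triggers a pooled-reference fallback (each band versus the rest
    of the cohort) with a warning.  Returns a DataFrame indexed by band
    label with columns hr, ci_low, ci_high, n, n_events.
    """
    time, event = icu_care_survival_data(cohort, horizon_days)
    band_idx = assign_bands(
        cohort.data[cohort.score_column("severity")].to_numpy(), convention
    )
    counts = {
        b: (int((band_idx == b.value).sum()),
            int(event[band_idx == b.value].sum()))
        for b in BANDS_ASCENDING
    }
    pooled = False
    if counts[reference][1] == 0:
        warnings.warn(
            f"reference band {reference} has no events; "
            "switching to pooled-reference hazard ratios",
            stacklevel=2,
        )
        pooled = True

    alpha = 1 - ci_level
    rows = {}
    if pooled:
        for band in BANDS_ASCENDING:
            n, d = counts[band]
            if n == 0 or d == 0:
                rows[str(band)] = (0.0, 0.0, float("nan"), n, d)
                continue
            frame = pd.DataFrame(
                {"T": time, "E": event.astype(int),
                 "in_band": (band_idx == band.value).astype(int)}
            )
            cph = CoxPHFitter(alpha=alpha)
            cph.fit(frame, duration_col="T", event_col="E")
            hr = float(np.exp(cph.params_["in_band"]))
            lo, hi = np.exp(
                cph.confidence_intervals_.loc["in_band"].to_numpy(float)
            )
            rows[str(band)] = (hr, float(lo), float(hi), n, d)
    else:
        cols = {}
        fit_bands = []
        for band in BANDS_ASCENDING:
            if band == reference or counts[band][1] == 0 or counts[band][0] == 0:
                continue
            cols[f"band_{band.value}"] = (band_idx == band.value).astype(int)
            fit_bands.append(band)
        keep = (band_idx == reference.value) | np.isin(
            band_idx, [b.value for b in fit_bands]
        )
        frame = pd.DataFrame(
            {"T": time[keep], "E": event[keep].astype(int),
             **{k: v[keep] for k, v in cols.items()}}
        )
        cph = CoxPHFitter(alpha=alpha)
        cph.fit(frame, duration_col="T", event_col="E")
        for band in BANDS_ASCENDING:
            n, d = counts[band]
            if band == reference:
                rows[str(band)] = (1.0, 1.0, 1.0, n, d)
            elif band in fit_bands:
                key = f"band_{band.value}"
                hr = float(np.exp(cph.params_[key]))
                lo, hi = np.exp(
                    cph.confidence_intervals_.loc[key].to_numpy(float)
                )
                rows[str(band)] = (hr, float(lo), float(hi), n, d)
            else:
                rows[str(band)] = (0.0, 0.0, float("nan"), n, d)

    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["hr", "ci_low", "ci_high", "n", "n_events"]
    )
    out.index.name = "band"
    return out
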