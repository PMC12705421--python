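"""Synthetic patient cohorts with the statistical structure the analysis assumes.

Two modes:

* **Exact reconstruction** (:func:`reconstruct_from_counts`): given printed
  band-by-truth counts for one endpoint, emit a patient-level cohort whose
  band contingency reproduces those counts cell-for-cell.  Scores within a
  band are uniform integers over the band interval (the within-band
  distribution is otherwise unconstrained), so band-level metrics are
  exact while any continuous-score quantity (e.g. AUROC) is
  band-resolution only.

* **Parametric generation** (:func:`generate`): a fully specified
  generative model (:class:`CohortSpec`) draws class labels, bands, scores,
  outcomes, qSOFA, covariates and treatment flags, reproducibly from a
  seed.  Defaults are calibrated to the validation-study marginals: a
  729-patient-style consensus mix (61.4% bacterial-only / 22.6%
  viral-only / 1.6% co-infection / 14.3% uninfected), 10.9% 7-day
  ICU-level-care risk, and per-class band masses equal to the published
  contingency fractions, so the implied band likelihood ratios are known
  in closed form (``mass_pos / mass_neg``).

The generator emulates the schema and the band-level structure of the
study data; it does not model gene expression or the classifier mapping
expression to scores.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .bands import BANDS_ASCENDING, BANDS_DESCENDING, Band, band_interval
from .cohort import Cohort, build_cohort, validate_patients

# ---------------------------------------------------------------------------
# Printed-count fixtures


@dataclasses.dataclass(frozen=True)
class BandCountFixture:
    """Per-band (n_positive, n_negative) counts for one endpoint."""

    endpoint_kind: str
    counts: Mapping[Band, Tuple[int, int]]

    @property
    def n_positive(self) -> int:
        return sum(a for a, _ in self.counts.values())

    @property
    def n_negative(self) -> int:
        return sum(b for _, b in self.counts.values())

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative


#: Published consensus-cohort band-by-truth counts (Very High → Very Low).
BACTERIAL_FIXTURE = BandCountFixture(
    "bacterial",
    {
        Band.VERY_HIGH: (165, 12),
        Band.HIGH: (107, 25),
        Band.MODERATE: (90, 46),
        Band.LOW: (85, 92),
        Band.VERY_LOW: (13, 94),
    },
)

VIRAL_FIXTURE = BandCountFixture(
    "viral",
    {
        Band.VERY_HIGH: (105, 8),
        Band.HIGH: (25, 33),
        Band.MODERATE: (22, 79),
        Band.LOW: (17, 166),
        Band.VERY_LOW: (8, 266),
    },
)

SEVERITY_FIXTURE = BandCountFixture(
    "severity",
    {
        Band.VERY_HIGH: (18, 13),
        Band.HIGH: (41, 139),
        Band.MODERATE: (38, 191),
        Band.LOW: (15, 288),
        Band.VERY_LOW: (10, 367),
    },
)


def study_fixtures() -> Dict[str, BandCountFixture]:
    """The three published band-count fixtures, keyed by endpoint."""
    return {
        "bacterial": BACTERIAL_FIXTURE,
        "viral": VIRAL_FIXTURE,
        "severity": SEVERITY_FIXTURE,
    }


def _base_frame(n: int) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i:06d}" for i in range(n)],
            "bacterial_score": 0,
            "viral_score": 0,
            "severity_score": 0,
            "final_bacterial": "Unlikely",
            "final_viral": "Unlikely",
            "mech_vent_day": pd.array([pd.NA] * n, dtype="Int64"),
            "vasopressor_day": pd.array([pd.NA] * n, dtype="Int64"),
            "rrt_day": pd.array([pd.NA] * n, dtype="Int64"),
            "icu_admit_day": pd.array([pd.NA] * n, dtype="Int64"),
            "death_day": pd.array([pd.NA] * n, dtype="Int64"),
            "qsofa": 0,
            "delta_sofa": pd.array([0] * n, dtype="Int64"),
            "lactate": 1.0,
            "crp": 10.0,
            "pct": 0.1,
            "wbc": 8.0,
            "antibiotics_day0": pd.array([0] * n, dtype="Int64"),
            "immunosuppressed": pd.array([0] * n, dtype="Int64"),
            "race": "Unknown",
            "site_id": "site-1",
            "followup_day": 28,
        }
    )
    return df


def _uniform_band_scores(rng, band_idx, convention="table"):
    lo = np.empty(len(band_idx), int)
    hi = np.empty(len(band_idx), int)
    for band in BANDS_ASCENDING:
        sel = band_idx == band.value
        l, h = band_interval(band, convention)
        lo[sel], hi[sel] = l, h
    return rng.integers(lo, hi + 1)


def reconstruct_from_counts(
    fixture: BandCountFixture,
    seed: Optional[int] = 0,
    convention: str = "table",
) -> Cohort:
    """Patient-level cohort whose band contingency equals *fixture* exactly.

    Scores are uniform integers within each band's interval (seeded,
    bit-reproducible).  For diagnostic endpoints the relevant final
    adjudication is Yes/No; for severity endpoints positives receive a
    vasopressor day drawn uniformly on 0–7 and negatives are event-free
    with 28-day follow-up.  An all-zero fixture raises (empty cohort).
    """
    rng = np.random.default_rng(seed)
    band_idx, labels = [], []
    for band in BANDS_DESCENDING:
        a, b = fixture.counts.get(band, (0, 0))
        band_idx += [band.value] * (a + b)
        labels += [True] * a + [False] * b
    band_idx = np.array(band_idx, int)
    labels = np.array(labels, bool)
    n = len(labels)
    df = _base_frame(n)
    if n == 0:  # all-zero fixture: an explicitly empty cohort
        return Cohort(df, fixture.endpoint_kind, "consensus",
                      np.zeros(0, bool), {})
    scores = _uniform_band_scores(rng, band_idx, convention)
    if fixture.endpoint_kind in ("bacterial", "viral"):
        df[f"{fixture.endpoint_kind}_score"] = scores
        df[f"final_{fixture.endpoint_kind}"] = np.where(labels, "Yes", "No")
        other = "viral" if fixture.endpoint_kind == "bacterial" else "bacterial"
        df[f"{other}_score"] = rng.integers(0, 51, size=n)
        return build_cohort(df, fixture.endpoint_kind, "consensus")
    # severity-type endpoint: plant a qualifying event day for positives
    df["severity_score"] = scores
    df["bacterial_score"] = rng.integers(0, 51, size=n)
    df["viral_score"] = rng.integers(0, 51, size=n)
    event_days = rng.integers(0, 8, size=n)
    df.loc[labels, "vasopressor_day"] = event_days[labels]
    return build_cohort(df, "severity", "consensus")


# ---------------------------------------------------------------------------
# Parametric generator


def _fixture_masses(fixture: BandCountFixture):
    pos = np.array([fixture.counts[b][0] for b in BANDS_ASCENDING], float)
    neg = np.array([fixture.counts[b][1] for b in BANDS_ASCENDING], float)
    return pos / pos.sum(), neg / neg.sum()


_BAC_POS_MASS, _BAC_NEG_MASS = _fixture_masses(BACTERIAL_FIXTURE)
_VIR_POS_MASS, _VIR_NEG_MASS = _fixture_masses(VIRAL_FIXTURE)
_SEV_POS_MASS, _SEV_NEG_MASS = _fixture_masses(SEVERITY_FIXTURE)

#: Default P(qSOFA = k | severity class), k = 0..3.  Calibrated so high
#: qSOFA (≥2) is markedly enriched among ICU-level-care positives.
_QSOFA_POS = (0.15, 0.25, 0.40, 0.20)
_QSOFA_NEG = (0.50, 0.35, 0.12, 0.03)

#: Default day-0 antibiotics rate per (bacterial-positive, band ordinal).
_ABX_POS = (0.70, 0.85, 0.90, 0.90, 0.98)  # Very Low .. Very High
_ABX_NEG = (0.25, 0.30, 0.45, 0.55, 0.60)


def _check_probs(name, vec, length):
    arr = np.asarray(vec, float)
    if arr.shape != (length,):
        raise ValueError(f"{name} must have length {length}")
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError(f"{name} entries must be probabilities in [0, 1]")
    if abs(arr.sum() - 1) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {arr.sum():.12f})")
    return arr


@dataclasses.dataclass
class CohortSpec:
    """Generative parameters for a synthetic emergency-department cohort.

    Band masses are 5-vectors over (Very Low, …, Very High) giving the
    probability of a score falling in each band, per class; the implied
    band likelihood ratio is ``band_mass_pos / band_mass_neg``.  Infection
    status is a four-way categorical (bacterial-only / viral-only /
    co-infection / uninfected); the severity endpoint is an independent
    Bernoulli.  qSOFA and ΔSOFA are drawn conditionally on the severity
    class, laboratory covariates log-normally per class, and day-0
    antibiotics per (bacterial status, bacterial band).
    """

    n: int = 10_000
    seed: int = 0
    # infection-status mix (sums to 1)
    p_bacterial_only: float = 448 / 729
    p_viral_only: float = 165 / 729
    p_coinfection: float = 12 / 729
    p_uninfected: float = 104 / 729
    prevalence_severity: float = 122 / 1120
    # band masses per axis and class (Very Low .. Very High)
    bacterial_mass_pos: tuple = tuple(_BAC_POS_MASS)
    bacterial_mass_neg: tuple = tuple(_BAC_NEG_MASS)
    viral_mass_pos: tuple = tuple(_VIR_POS_MASS)
    viral_mass_neg: tuple = tuple(_VIR_NEG_MASS)
    severity_mass_pos: tuple = tuple(_SEV_POS_MASS)
    severity_mass_neg: tuple = tuple(_SEV_NEG_MASS)
    # conditional models
    qsofa_pos: tuple = _QSOFA_POS
    qsofa_neg: tuple = _QSOFA_NEG
    event_day_probs: tuple = (1 / 8,) * 8  # days 0..7 given a severe course
    p_death_given_severe: float = 0.25
    p_death_given_not: float = 0.02
    antibiotics_pos: tuple = _ABX_POS
    antibiotics_neg: tuple = _ABX_NEG
    delta_sofa_mean_pos: float = 3.0
    delta_sofa_mean_neg: float = 0.6
    # log-normal lab models: (median, sigma of log)
    lactate_pos: tuple = (3.0, 0.5)
    lactate_neg: tuple = (1.4, 0.4)
    crp_pos: tuple = (90.0, 1.0)
    crp_neg: tuple = (25.0, 1.1)
    pct_pos: tuple = (1.0, 1.5)
    pct_neg: tuple = (0.15, 1.2)
    wbc_pos: tuple = (12.5, 0.35)
    wbc_neg: tuple = (9.0, 0.35)
    p_immunosuppressed: float = 0.18
    race_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"White": 0.632, "Black": 0.306, "Other": 0.062}
    )
    n_sites: int = 22
    band_convention: str = "table"

    def validate(self) -> "CohortSpec":
        mix = np.array(
            [self.p_bacterial_only, self.p_viral_only,
             self.p_coinfection, self.p_uninfected]
        )
        _check_probs("infection-status mix", mix, 4)
        for name in (
            "bacterial_mass_pos", "bacterial_mass_neg",
            "viral_mass_pos", "viral_mass_neg",
            "severity_mass_pos", "severity_mass_neg",
        ):
            _check_probs(name, getattr(self, name), 5)
        _check_probs("qsofa_pos", self.qsofa_pos, 4)
        _check_probs("qsofa_neg", self.qsofa_neg, 4)
        _check_probs("event_day_probs", self.event_day_probs, 8)
        if not 0 <= self.prevalence_severity <= 1:
            raise ValueError("prevalence_severity must be in [0, 1]")
        return self

    @property
    def prevalence_bacterial(self) -> float:
        return self.p_bacterial_only + self.p_coinfection

    @property
    def prevalence_viral(self) -> float:
        return self.p_viral_only + self.p_coinfection

    def implied_band_lrs(self, axis: str = "bacterial") -> np.ndarray:
        """Theoretical band LRs (Very Low .. Very High): mass_pos / mass_neg."""
        pos = np.asarray(getattr(self, f"{axis}_mass_pos"), float)
        neg = np.asarray(getattr(self, f"{axis}_mass_neg"), float)
        return pos / neg

    def implied_band_event_rate(self, axis: str = "severity") -> np.ndarray:
        """P(positive | band) per band, from Bayes at the spec prevalence."""
        prev = {
            "bacterial": self.prevalence_bacterial,
            "viral": self.prevalence_viral,
            "severity": self.prevalence_severity,
        }[axis]
        pos = np.asarray(getattr(self, f"{axis}_mass_pos"), float)
        neg = np.asarray(getattr(self, f"{axis}_mass_neg"), float)
        joint_pos = prev * pos
        return joint_pos / (joint_pos + (1 - prev) * neg)


def _lognormal(rng, n, median_sigma):
    median, sigma = median_sigma
    return np.exp(rng.normal(np.log(median), sigma, size=n))


def generate(spec: CohortSpec) -> pd.DataFrame:
    """Draw a patient DataFrame from the generative model in *spec*.

    Fully reproducible: the same spec (including seed) yields an identical
    frame.  Band assignments on the three axes are conditionally
    independent given the class labels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    df = _base_frame(n)

    status = rng.choice(
        4,
        size=n,
        p=[spec.p_bacterial_only, spec.p_viral_only,
           spec.p_coinfection, spec.p_uninfected],
    )
    bacterial = (status == 0) | (status == 2)
    viral = (status == 1) | (status == 2)
    severe = rng.random(n) < spec.prevalence_severity

    for axis, positive in (("bacterial", bacterial), ("viral", viral),
                           ("severity", severe)):
        mass_pos = np.asarray(getattr(spec, f"{axis}_mass_pos"))
        mass_neg = np.asarray(getattr(spec, f"{axis}_mass_neg"))
        band_idx = np.empty(n, int)
        n_pos = int(positive.sum())
        band_idx[positive] = rng.choice(5, size=n_pos, p=mass_pos)
        band_idx[~positive] = rng.choice(5, size=n - n_pos, p=mass_neg)
        df[f"{axis}_score"] = _uniform_band_scores(
            rng, band_idx, spec.band_convention
        )

    df["final_bacterial"] = np.where(bacterial, "Yes", "No")
    df["final_viral"] = np.where(viral, "Yes", "No")

    # severe course: at least one ICU-level-care component within 7 days,
    # component mix loosely matching the published component shares
    n_sev = int(severe.sum())
    comp = rng.random((n_sev, 3)) < np.array([0.52, 0.81, 0.19])
    none = ~comp.any(axis=1)
    comp[none, 1] = True  # vasopressors, the most common component
    days = rng.choice(8, size=(n_sev, 3), p=spec.event_day_probs)
    for j, col in enumerate(("mech_vent_day", "vasopressor_day", "rrt_day")):
        vals = pd.array([pd.NA] * n, dtype="Int64")
        idx = np.flatnonzero(severe)[comp[:, j]]
        vals[idx] = days[comp[:, j], j]
        df[col] = vals

    p_death = np.where(severe, spec.p_death_given_severe, spec.p_death_given_not)
    died = rng.random(n) < p_death
    death_day = pd.array([pd.NA] * n, dtype="Int64")
    death_day[died] = rng.integers(1, 29, size=int(died.sum()))
    df["death_day"] = death_day

    icu = severe | (rng.random(n) < 0.05)
    icu_day = pd.array([pd.NA] * n, dtype="Int64")
    icu_day[icu] = rng.integers(0, 8, size=int(icu.sum()))
    df["icu_admit_day"] = icu_day

    qsofa = np.where(
        severe,
        rng.choice(4, size=n, p=spec.qsofa_pos),
        rng.choice(4, size=n, p=spec.qsofa_neg),
    )
    df["qsofa"] = qsofa
    delta = np.where(
        severe,
        rng.poisson(spec.delta_sofa_mean_pos, size=n),
        rng.poisson(spec.delta_sofa_mean_neg, size=n),
    )
    df["delta_sofa"] = pd.array(delta, dtype="Int64")

    df["lactate"] = np.where(
        severe, _lognormal(rng, n, spec.lactate_pos),
        _lognormal(rng, n, spec.lactate_neg),
    ).round(2)
    for col, positive in (("crp", bacterial), ("pct", bacterial),
                          ("wbc", bacterial)):
        pos_m = getattr(spec, f"{col}_pos")
        neg_m = getattr(spec, f"{col}_neg")
        df[col] = np.where(
            positive, _lognormal(rng, n, pos_m), _lognormal(rng, n, neg_m)
        ).round(2)

    bac_band = np.asarray(
        _band_ordinals(df["bacterial_score"].to_numpy(), spec.band_convention)
    )
    abx_rate = np.where(
        bacterial,
        np.asarray(spec.antibiotics_pos)[bac_band],
        np.asarray(spec.antibiotics_neg)[bac_band],
    )
    df["antibiotics_day0"] = pd.array(
        (rng.random(n) < abx_rate).astype(int), dtype="Int64"
    )

    df["immunosuppressed"] = pd.array(
        (rng.random(n) < spec.p_immunosuppressed).astype(int), dtype="Int64"
    )
    races = list(spec.race_probs)
    df["race"] = rng.choice(races, size=n, p=list(spec.race_probs.values()))
    df["site_id"] = np.array(
        [f"site-{i + 1}" for i in rng.integers(0, spec.n_sites, size=n)]
    )
    return validate_patients(df)


def _band_ordinals(scores, convention):
    from .bands import assign_bands

    return assign_bands(scores, convention)


# ---------------------------------------------------------------------------
# Prose-constrained clinical-utility fixtures


def antibiotics_utility_cohort(seed: int = 0) -> Cohort:
    """Consensus bacterial cohort with day-0 antibiotics flags attached.

    The band-by-adjudication structure is the published 729-patient
    contingency; antibiotics flags are planted so that 33
    adjudicated-bacterial patients are untreated on day 0 (bands
    Moderate/High/Very High: 10/11/3, remainder in Low/Very Low) and 103
    adjudicated-non-bacterial patients are treated (62 in Low ∪ Very Low).
    Within-band splits not pinned down by the published counts are
    synthetic choices recorded here: untreated-bacterial Low/Very Low =
    5/4; treated-non-bacterial = 7/14/20/27/35 from Very High to Very Low.
    """
    cohort = reconstruct_from_counts(BACTERIAL_FIXTURE, seed=seed)
    df = cohort.data
    band_idx = _band_ordinals(df["bacterial_score"].to_numpy(), "table")
    y = cohort.y
    abx = np.ones(len(df), int)
    untreated_pos = {  # band ordinal -> count untreated among bacterial-Yes
        Band.VERY_HIGH.value: 3, Band.HIGH.value: 11, Band.MODERATE.value: 10,
        Band.LOW.value: 5, Band.VERY_LOW.value: 4,
    }
    treated_neg = {  # band ordinal -> count treated among bacterial-No
        Band.VERY_HIGH.value: 7, Band.HIGH.value: 14, Band.MODERATE.value: 20,
        Band.LOW.value: 27, Band.VERY_LOW.value: 35,
    }
    for band_val, k in untreated_pos.items():
        idx = np.flatnonzero(y & (band_idx == band_val))[:k]
        abx[idx] = 0
    abx[~y] = 0
    for band_val, k in treated_neg.items():
        idx = np.flatnonzero(~y & (band_idx == band_val))[:k]
        abx[idx] = 1
    df = df.copy()
    df["antibiotics_day0"] = pd.array(abx, dtype="Int64")
    return Cohort(df, cohort.endpoint_kind, cohort.inclusion_rule, y,
                  cohort.excluded)


def lactate_utility_cohort(seed: int = 0) -> Cohort:
    """Prognostic cohort with lactate zones planted to the published prose.

    Built on the published 1,120-patient severity contingency.  213
    patients get indeterminate lactate (2–4 mmol/l); 58 of them have a
    severe course (ICU-level care), of whom 46 sit in Moderate-or-higher
    Severity bands (20/16/10 Moderate/High/Very High — a synthetic split)
    and 12 in Low/Very Low (7/5).  All other patients get lactate outside
    the indeterminate zone.
    """
    cohort = reconstruct_from_counts(SEVERITY_FIXTURE, seed=seed)
    df = cohort.data.copy()
    band_idx = _band_ordinals(df["severity_score"].to_numpy(), "table")
    y = cohort.y
    lactate = np.full(len(df), 1.2)
    indeterminate_severe = {
        Band.MODERATE.value: 20, Band.HIGH.value: 16, Band.VERY_HIGH.value: 10,
        Band.LOW.value: 7, Band.VERY_LOW.value: 5,
    }
    chosen = []
    for band_val, k in indeterminate_severe.items():
        idx = np.flatnonzero(y & (band_idx == band_val))[:k]
        if len(idx) < k:
            raise AssertionError("fixture short of severe patients in band")
        chosen.extend(idx)
    lactate[np.array(chosen)] = 3.0
    # fill the zone up to 213 with non-severe patients
    n_more = 213 - len(chosen)
    nonsevere = np.flatnonzero(~y)[:n_more]
    lactate[nonsevere] = 2.5
    df["lactate"] = lactate
    return Cohort(df, cohort.endpoint_kind, cohort.inclusion_rule, y,
                  cohort.excluded)
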