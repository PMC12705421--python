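import numpy as np
import pandas as pd
import pytest

import bandeval as bv

# Published per-band accuracy rows (Very High → Very Low), at printed
# rounding: (sensitivity %, specificity %, LR, relative frequency %,
# probability-in-band %).
PRINTED_TABLES = {
    "bacterial": {
        "Very High": (35.9, 95.5, 8.04, 24.3, 93.2),
        "High": (23.3, 90.7, 2.50, 18.1, 81.1),
        "Moderate": (19.6, 82.9, 1.14, 18.7, 66.2),
        "Low": (81.5, 34.2, 0.54, 24.3, 48.0),
        "Very Low": (97.2, 34.9, 0.08, 14.7, 12.1),
    },
    "viral": {
        "Very High": (59.3, 98.6, 40.93, 15.5, 92.9),
        "High": (14.1, 94.0, 2.36, 8.0, 43.1),
        "Moderate": (12.4, 85.7, 0.87, 13.9, 21.8),
        "Low": (90.4, 30.1, 0.32, 25.1, 9.3),
        "Very Low": (95.5, 48.2, 0.09, 37.6, 2.9),
    },
    "severity": {
        "Very High": (14.8, 98.7, 11.33, 2.8, 58.1),
        "High": (33.6, 86.1, 2.41, 16.1, 22.8),
        "Moderate": (31.1, 80.9, 1.63, 20.4, 16.6),
        "Low": (87.7, 28.9, 0.43, 27.1, 5.0),
        "Very Low": (91.8, 36.8, 0.22, 33.7, 2.7),
    },
}

# Published per-band likelihood ratios at printed rounding,
# Very Low → Very High.
PRINTED_LRS = {
    "bacterial": (0.08, 0.54, 1.14, 2.50, 8.04),
    "viral": (0.09, 0.32, 0.87, 2.36, 40.93),
    "severity": (0.22, 0.43, 1.63, 2.41, 11.33),
}


@pytest.fixture(scope="session")
def study_cohorts():
    """Count-matched reconstructions of the three published cohorts."""
    return {
        name: bv.reconstruct_from_counts(fixture, seed=7)
        for name, fixture in bv.study_fixtures().items()
    }


@pytest.fixture(scope="session")
def study_tables(study_cohorts):
    return {
        name: bv.build_band_contingency(cohort)
        for name, cohort in study_cohorts.items()
    }


def make_patients(**overrides) -> pd.DataFrame:
    """Small hand-built patient frame; column overrides are broadcast."""
    n = max(
        (len(v) for v in overrides.values() if isinstance(v, (list, tuple))),
        default=4,
    )
    base = {
        "patient_id": [f"p{i}" for i in range(n)],
        "bacterial_score": 25,
        "viral_score": 5,
        "severity_score": 15,
        "final_bacterial": "Yes",
        "final_viral": "No",
        "mech_vent_day": pd.NA,
        "vasopressor_day": pd.NA,
        "rrt_day": pd.NA,
        "icu_admit_day": pd.NA,
        "death_day": pd.NA,
        "qsofa": 1,
        "delta_sofa": 0,
        "lactate": 1.5,
        "crp": 20.0,
        "pct": 0.2,
        "wbc": 9.0,
        "antibiotics_day0": 1,
        "immunosuppressed": 0,
        "race": "White",
        "site_id": "site-1",
        "followup_day": 28,
    }
    base.update(overrides)
    df = pd.DataFrame(base)
    for col in ("mech_vent_day", "vasopressor_day", "rrt_day",
                "icu_admit_day", "death_day", "delta_sofa",
                "antibiotics_day0", "immunosuppressed"):
        df[col] = pd.array(df[col], dtype="Int64")
    return df
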