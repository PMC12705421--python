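"""Clinical-utility analyses: antibiotics, sepsis surrogate, lactate zones."""

import math

import numpy as np
import pandas as pd
import pytest

import bandeval as bv
from bandeval import Band
from bandeval.metrics import round_half_up
from bandeval.utility import sepsis_surrogate

from .conftest import make_patients


class TestAntibioticReclassification:
    def test_prose_constrained_fixture_counts(self):
        cohort = bv.antibiotics_utility_cohort(seed=0)
        report = bv.antibiotic_reclassification(cohort)
        under = report["undertreated"]
        over = report["overtreated"]
        assert (under.n_total, under.n_flagged) == (33, 24)
        assert round_half_up(under.pct_flagged, 1) == 72.7
        assert (over.n_total, over.n_flagged) == (103, 62)
        assert round_half_up(over.pct_flagged, 1) == 60.2

    def test_perfect_targeting_leaves_both_groups_empty(self):
        df = make_patients(
            final_bacterial=["Yes", "Yes", "No", "No"],
            antibiotics_day0=[1, 1, 0, 0],
        )
        cohort = bv.build_cohort(df, "bacterial", "forced")
        report = bv.antibiotic_reclassification(cohort)
        assert report["undertreated"].n_total == 0
        assert report["overtreated"].n_total == 0
        assert math.isnan(report["undertreated"].pct_flagged)

    def test_partition_of_untreated_patients(self):
        cohort = bv.antibiotics_utility_cohort(seed=0)
        df = cohort.data
        untreated = (df["antibiotics_day0"] == 0) & df[
            "final_bacterial"
        ].isin(["Yes", "No"])
        under = bv.antibiotic_reclassification(cohort)["undertreated"]
        correctly_untreated = (
            (df["final_bacterial"] == "No") & (df["antibiotics_day0"] == 0)
        ).sum()
        assert under.n_total + int(correctly_untreated) == int(
            untreated.sum()
        )


class TestSepsisSurrogate:
    def test_definition_arms(self):
        df = make_patients(
            final_bacterial=["Yes", "No", "Yes", "Yes"],
            delta_sofa=[3, 5, 0, 0],
            vasopressor_day=[pd.NA, pd.NA, 1, pd.NA],
        )
        flags = sepsis_surrogate(df)
        # ΔSOFA arm; non-bacterial is always false; ICU-care arm; neither
        assert flags.tolist() == [True, False, True, False]

    def test_missing_delta_sofa_with_negative_endpoint_is_undetermined(self):
        df = make_patients(
            final_bacterial=["Yes"], delta_sofa=[pd.NA]
        )
        assert sepsis_surrogate(df).isna().iloc[0]

    def test_monotone_adding_intervention_never_unflags(self):
        base = make_patients(
            final_bacterial=["Yes"] * 3,
            delta_sofa=[0, 2, 3],
        )
        before = sepsis_surrogate(base)
        with_event = base.copy()
        with_event["rrt_day"] = pd.array([2, 2, 2], dtype="Int64")
        after = sepsis_surrogate(with_event)
        assert ((before != True) | (after == True)).all()  # noqa: E712


class TestSepsisCrosstab:
    def test_point_mass_cell(self):
        df = make_patients(
            bacterial_score=[45, 45, 5, 5],
            severity_score=[45, 45, 5, 5],
            final_bacterial=["Yes", "Yes", "No", "No"],
            delta_sofa=[3, 3, 0, 0],
        )
        cohort = bv.build_cohort(df, "severity")
        pct, n = bv.sepsis_crosstab(cohort)
        assert pct.loc["Very High", "Very High"] == 100.0
        assert pct.loc["Very Low", "Very Low"] == 0.0
        assert n.to_numpy().sum() == 4

    def test_planted_cell_rates_recovered(self):
        rng = np.random.default_rng(12)
        n = 40_000
        bac_band = rng.integers(0, 5, n)
        sev_band = rng.integers(0, 5, n)
        # planted surrogate rate rises with both bands
        rate = 0.02 + 0.08 * bac_band + 0.06 * sev_band
        hit = rng.random(n) < rate
        df = make_patients(
            patient_id=[f"p{i}" for i in range(n)],
            bacterial_score=(bac_band * 10 + 5).tolist(),
            severity_score=(sev_band * 10 + 5).tolist(),
            final_bacterial=["Yes"] * n,
            delta_sofa=np.where(hit, 3, 0).tolist(),
        )
        cohort = bv.build_cohort(df, "severity")
        pct, counts = bv.sepsis_crosstab(cohort)
        for i, bb in enumerate(bv.BANDS_ASCENDING):
            for j, sb in enumerate(bv.BANDS_ASCENDING):
                expected = 100 * (0.02 + 0.08 * i + 0.06 * j)
                cell_n = counts.loc[str(bb), str(sb)]
                se = math.sqrt(expected * (100 - expected) / cell_n)
                assert abs(pct.loc[str(bb), str(sb)] - expected) < 3 * se

    def test_high_high_cell_dominates_low_cells_on_study_like_data(self):
        df = bv.generate(bv.CohortSpec(n=30_000, seed=5))
        cohort = bv.build_cohort(df, "severity")
        pct, _ = bv.sepsis_crosstab(cohort)
        low_cells = [
            pct.loc["Low", "Low"], pct.loc["Low", "Very Low"],
            pct.loc["Very Low", "Low"], pct.loc["Very Low", "Very Low"],
        ]
        assert pct.loc["Very High", "Very High"] > max(low_cells) + 20

    def test_marginal_aggregation_consistency(self):
        """Pooled rate over high Bacterial bands equals the weighted
        cross-tab marginal."""
        df = bv.generate(bv.CohortSpec(n=10_000, seed=6))
        cohort = bv.build_cohort(df, "severity")
        pct, counts = bv.sepsis_crosstab(cohort)
        flags = sepsis_surrogate(cohort.data)
        bac_idx = bv.assign_bands(cohort.data["bacterial_score"].to_numpy())
        pooled_sel = (bac_idx >= Band.HIGH.value) & flags.notna().to_numpy()
        pooled = 100 * (
            (flags[pooled_sel] == True).sum() / pooled_sel.sum()  # noqa: E712
        )
        rows = ["Very High", "High"]
        weighted = (
            (pct.loc[rows] * counts.loc[rows]).sum().sum()
            / counts.loc[rows].sum().sum()
        )
        assert weighted == pytest.approx(pooled, abs=1e-9)


class TestLactateZones:
    def test_prose_constrained_fixture(self):
        cohort = bv.lactate_utility_cohort(seed=0)
        zones = bv.lactate_zone_analysis(cohort)
        mid = zones["indeterminate"]
        assert mid.n == 213
        assert mid.n_severe == 58
        assert mid.n_severe_flagged == 46
        assert round_half_up(mid.pct_flagged, 1) == 79.3

    def test_boundary_values_fall_in_indeterminate_zone(self):
        df = make_patients(lactate=[2.0, 4.0, 1.99, 4.01])
        cohort = bv.build_cohort(df, "severity")
        zones = bv.lactate_zone_analysis(cohort)
        assert zones["indeterminate"].n == 2
        assert zones["low"].n == 1
        assert zones["high"].n == 1

    def test_all_low_lactate_leaves_other_zones_empty(self):
        df = make_patients(lactate=[0.8, 1.1, 1.9])
        cohort = bv.build_cohort(df, "severity")
        zones = bv.lactate_zone_analysis(cohort)
        assert zones["indeterminate"].n == 0
        assert zones["high"].n == 0

    def test_negative_lactate_rejected(self):
        df = make_patients(lactate=[-0.5])
        cohort = bv.build_cohort(df, "severity")
        with pytest.raises(ValueError, match="lactate"):
            bv.lactate_zone_analysis(cohort)
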