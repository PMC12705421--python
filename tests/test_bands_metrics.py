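"""Band assignment and the band-stratified accuracy metrics."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bandeval as bv
from bandeval import Band
from bandeval.metrics import BAND_ROLES, round_half_up

from .conftest import PRINTED_TABLES


class TestAssignBand:
    @pytest.mark.parametrize(
        "score, band",
        [
            (0, Band.VERY_LOW),
            (10, Band.VERY_LOW),
            (11, Band.LOW),
            (20, Band.LOW),
            (21, Band.MODERATE),
            (29, Band.MODERATE),
            (30, Band.HIGH),
            (39, Band.HIGH),
            (40, Band.VERY_HIGH),
            (45, Band.VERY_HIGH),
            (50, Band.VERY_HIGH),
        ],
    )
    def test_table_convention_intervals(self, score, band):
        assert bv.assign_band(score) is band

    @pytest.mark.parametrize(
        "score, band",
        [(30, Band.MODERATE), (31, Band.HIGH), (40, Band.HIGH),
         (41, Band.VERY_HIGH)],
    )
    def test_prose_convention_shifts_upper_bounds(self, score, band):
        assert bv.assign_band(score, convention="prose") is band

    @pytest.mark.parametrize("bad", [-1, 51, 12.5, "30"])
    def test_invalid_scores_rejected(self, bad):
        with pytest.raises((ValueError, TypeError)):
            bv.assign_band(bad)

    @given(score=st.integers(0, 50))
    @settings(derandomize=True, max_examples=51)
    def test_vectorised_matches_scalar(self, score):
        assert bv.assign_bands([score])[0] == bv.assign_band(score).value


class TestBandContingency:
    def test_study_fixture_cells_are_exact(self, study_tables):
        for name, fixture in bv.study_fixtures().items():
            table = study_tables[name]
            for band, (a, b) in fixture.counts.items():
                assert table.cell(band) == (a, b)
            assert table.n_positive == fixture.n_positive
            assert table.n_negative == fixture.n_negative

    def test_single_patient_cohort(self):
        from .conftest import make_patients

        df = make_patients(bacterial_score=[45], final_bacterial=["Yes"])
        cohort = bv.build_cohort(df, "bacterial")
        table = bv.build_band_contingency(cohort)
        assert table.cell(Band.VERY_HIGH) == (1, 0)
        assert table.total == 1

    def test_counts_partition_cohort(self, study_cohorts, study_tables):
        for name in study_tables:
            assert study_tables[name].total == len(study_cohorts[name])


def _random_table(rng):
    counts = {
        band: (int(rng.integers(0, 40)), int(rng.integers(0, 40)))
        for band in bv.BANDS_ASCENDING
    }
    counts[Band.MODERATE] = (counts[Band.MODERATE][0] + 1,
                             counts[Band.MODERATE][1] + 1)
    return bv.BandTable(counts)


class TestBandMetrics:
    @pytest.mark.parametrize("endpoint", ["bacterial", "viral", "severity"])
    def test_printed_rows_reproduced(self, study_tables, endpoint):
        """Every printed cell (sens, spec, LR, rel freq, probability)."""
        table = study_tables[endpoint]
        rows = bv.band_metrics_table(table).set_index("band")
        for band, (sens, spec, lr, rf, prob) in PRINTED_TABLES[
            endpoint
        ].items():
            row = rows.loc[band]
            assert round_half_up(row["sensitivity"], 1) == sens
            assert round_half_up(row["specificity"], 1) == spec
            assert round_half_up(row["lr"], 2) == lr
            assert round_half_up(row["rel_freq"], 1) == rf
            assert round_half_up(row["prob_in_band"], 1) == prob

    def test_lr_equals_sens_over_one_minus_spec_exactly(self):
        """Rule-in identity LR = sens / (100 − spec), exact rationals."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            table = _random_table(rng)
            for band in bv.BANDS_ASCENDING:
                a, b = table.cell(band)
                if a == 0 or b == 0:
                    continue
                lr = bv.band_likelihood_ratio(table, band, exact=True)
                sens, spec = bv.band_rule_metrics(
                    table, band, band_role="rule_in", exact=True
                )
                assert lr == sens / (100 - spec)

    def test_conservation_of_totals_and_frequencies(self, study_tables):
        for table in study_tables.values():
            rel = sum(
                bv.relative_frequency(table, band, exact=True)
                for band in bv.BANDS_ASCENDING
            )
            assert rel == 100

    def test_uninformative_table_has_unit_lrs(self):
        table = bv.BandTable(
            {band: (10, 20) for band in bv.BANDS_ASCENDING}
        )
        for band in bv.BANDS_ASCENDING:
            assert bv.band_likelihood_ratio(table, band) == 1.0

    def test_lr_monotone_across_bands_on_all_fixtures(self, study_tables):
        for table in study_tables.values():
            lrs = [
                bv.band_likelihood_ratio(table, band)
                for band in bv.BANDS_ASCENDING
            ]
            assert lrs == sorted(lrs)

    def test_zero_negative_band_gives_infinite_lr(self):
        counts = {band: (10, 10) for band in bv.BANDS_ASCENDING}
        counts[Band.VERY_HIGH] = (5, 0)
        table = bv.BandTable(counts)
        assert bv.band_likelihood_ratio(table, Band.VERY_HIGH) == math.inf

    def test_empty_band_probability_is_absent_not_zero(self):
        counts = {band: (10, 10) for band in bv.BANDS_ASCENDING}
        counts[Band.VERY_HIGH] = (0, 0)
        table = bv.BandTable(counts)
        assert math.isnan(bv.band_probability(table, Band.VERY_HIGH))
        assert math.isnan(bv.band_likelihood_ratio(table, Band.VERY_HIGH))

    def test_probability_in_balanced_band_is_fifty(self):
        table = bv.BandTable({band: (7, 7) for band in bv.BANDS_ASCENDING})
        assert bv.band_probability(table, Band.LOW) == 50.0

    def test_single_class_table_rejected(self):
        table = bv.BandTable({band: (3, 0) for band in bv.BANDS_ASCENDING})
        with pytest.raises(ValueError, match="both classes"):
            bv.band_rule_metrics(table, Band.LOW)

    def test_moderate_uses_rule_in_formulas_but_is_not_actionable(self):
        assert BAND_ROLES[Band.MODERATE] == "neutral"
        assert Band.MODERATE not in bv.ACTIONABLE_BANDS


class TestLrConfidenceInterval:
    def test_log_normal_matches_closed_form_on_bacterial_very_high(
        self, study_tables
    ):
        lo, hi = bv.lr_confidence_interval(
            study_tables["bacterial"], Band.VERY_HIGH, level=0.80
        )
        assert lo == pytest.approx(5.55, abs=0.01)
        assert hi == pytest.approx(11.64, abs=0.01)

    def test_symmetric_table_interval_contains_one(self):
        table = bv.BandTable({band: (8, 8) for band in bv.BANDS_ASCENDING})
        lo, hi = bv.lr_confidence_interval(table, Band.MODERATE)
        assert lo < 1.0 < hi

    def test_bootstrap_handles_zero_positive_cell(self):
        counts = {band: (10, 10) for band in bv.BANDS_ASCENDING}
        counts[Band.VERY_LOW] = (0, 12)
        table = bv.BandTable(counts)
        with pytest.raises(ValueError, match="bootstrap"):
            bv.lr_confidence_interval(table, Band.VERY_LOW)
        lo, hi = bv.lr_confidence_interval(
            table, Band.VERY_LOW, method="bootstrap", seed=0
        )
        assert lo == 0.0
        assert hi >= lo

    def test_bootstrap_reproducible_and_brackets_log_normal(
        self, study_tables
    ):
        table = study_tables["bacterial"]
        b1 = bv.lr_confidence_interval(
            table, Band.HIGH, method="bootstrap", n_boot=4000, seed=42
        )
        b2 = bv.lr_confidence_interval(
            table, Band.HIGH, method="bootstrap", n_boot=4000, seed=42
        )
        assert b1 == b2
        ln = bv.lr_confidence_interval(table, Band.HIGH)
        assert b1[0] == pytest.approx(ln[0], rel=0.1)
        assert b1[1] == pytest.approx(ln[1], rel=0.1)


class TestSummaries:
    def test_fold_ranges_match_reported_scale(self, study_tables):
        rows = {
            k: bv.band_metrics_table(t) for k, t in study_tables.items()
        }
        assert bv.lr_fold_range(rows["bacterial"]) == pytest.approx(100.5)
        assert bv.lr_fold_range(rows["viral"]) >= 400
        assert bv.lr_fold_range(rows["severity"]) >= 50

    def test_constant_lrs_fold_range_is_one(self):
        assert bv.lr_fold_range([2.0, 2.0, 2.0]) == 1.0

    def test_infinite_lr_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="non-finite"):
            assert bv.lr_fold_range([0.5, math.inf, 2.0]) == 4.0

    def test_actionable_fractions_match_study(self, study_cohorts):
        bacterial = bv.actionable_fraction(
            study_cohorts["bacterial"], axes=("bacterial",)
        )["bacterial"]
        viral = bv.actionable_fraction(
            study_cohorts["viral"], axes=("viral",)
        )["viral"]
        severity = bv.actionable_fraction(
            study_cohorts["severity"], axes=("severity",)
        )["severity"]
        assert round_half_up(bacterial, 1) == 81.3
        assert round_half_up(viral, 1) == 86.1
        assert round_half_up(severity, 1) == 79.6

    def test_all_moderate_cohort_has_zero_actionable(self):
        from .conftest import make_patients

        df = make_patients(bacterial_score=[25] * 6)
        cohort = bv.build_cohort(df, "bacterial", "forced")
        assert bv.actionable_fraction(cohort)["bacterial"] == 0.0
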