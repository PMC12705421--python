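"""qSOFA stratification, the combined rule, and Fisher's exact test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bandeval as bv
from bandeval import Band

from .conftest import make_patients


def _generated_severity_cohort(n=50_000, seed=31):
    spec = bv.CohortSpec(n=n, seed=seed)
    return spec, bv.build_cohort(bv.generate(spec), "severity")


class TestStratifiedRates:
    def test_all_negative_cohort_rates_are_zero(self):
        df = make_patients(qsofa=[0, 1, 2, 3] * 5)
        cohort = bv.build_cohort(df, "severity")
        rates = bv.stratified_outcome_rates(cohort)
        assert rates["qsofa_low"].overall_rate == 0.0
        assert rates["qsofa_high"].overall_rate == 0.0

    def test_stratum_rates_average_to_overall(self):
        _, cohort = _generated_severity_cohort(n=20_000)
        rates = bv.stratified_outcome_rates(cohort)
        lo, hi = rates["qsofa_low"], rates["qsofa_high"]
        assert lo.n + hi.n == len(cohort)
        pooled = (lo.n * lo.overall_rate + hi.n * hi.overall_rate) / (
            lo.n + hi.n
        )
        assert pooled == pytest.approx(100 * cohort.y.mean(), abs=1e-9)

    def test_generative_per_band_rates_recovered(self):
        """Per-(stratum, band) event rates match the closed-form rates
        implied by the generative model (qSOFA ⟂ outcome given class)."""
        spec, cohort = _generated_severity_cohort()
        rates = bv.stratified_outcome_rates(cohort)
        prev = spec.prevalence_severity
        mass_pos = np.asarray(spec.severity_mass_pos)
        mass_neg = np.asarray(spec.severity_mass_neg)
        stratum_prob = {
            "qsofa_low": (sum(spec.qsofa_pos[:2]), sum(spec.qsofa_neg[:2])),
            "qsofa_high": (sum(spec.qsofa_pos[2:]), sum(spec.qsofa_neg[2:])),
        }
        for stratum in ("qsofa_low", "qsofa_high"):
            s_pos, s_neg = stratum_prob[stratum]
            joint_pos = prev * mass_pos * s_pos
            joint_neg = (1 - prev) * mass_neg * s_neg
            theory = 100 * joint_pos / (joint_pos + joint_neg)
            for band, expected in zip(bv.BANDS_ASCENDING, theory):
                cell = rates[stratum].per_band[band]
                if cell.n < 200:
                    continue
                se = math.sqrt(expected * (100 - expected) / cell.n)
                assert abs(cell.rate - expected) < 3 * se + 1e-9

    def test_high_stratum_is_enriched_for_events(self):
        _, cohort = _generated_severity_cohort(n=20_000)
        rates = bv.stratified_outcome_rates(cohort)
        assert (
            rates["qsofa_high"].overall_rate
            > rates["qsofa_low"].overall_rate
        )

    def test_empty_stratum_warned(self):
        df = make_patients(qsofa=[0, 1, 0, 1])
        cohort = bv.build_cohort(df, "severity")
        with pytest.warns(UserWarning, match="empty"):
            rates = bv.stratified_outcome_rates(cohort)
        assert math.isnan(rates["qsofa_high"].overall_rate)


class TestCombinedRule:
    def test_all_positives_high_qsofa_saturates_both(self):
        df = make_patients(
            qsofa=[3, 3, 0, 0],
            vasopressor_day=[1, 2, pd.NA, pd.NA],
        )
        cohort = bv.build_cohort(df, "severity")
        alone, combined = bv.combined_rule_sensitivity(cohort)
        assert alone == combined == 100.0

    def test_very_low_cutoff_flags_everyone(self):
        df = make_patients(
            qsofa=[0] * 6,
            severity_score=[5, 15, 25, 35, 45, 10],
            vasopressor_day=[1, pd.NA, 3, pd.NA, 2, pd.NA],
        )
        cohort = bv.build_cohort(df, "severity")
        _, combined = bv.combined_rule_sensitivity(cohort, Band.VERY_LOW)
        assert combined == 100.0

    def test_combined_matches_enumeration_oracle(self):
        _, cohort = _generated_severity_cohort(n=5000, seed=8)
        alone, combined = bv.combined_rule_sensitivity(cohort, Band.MODERATE)
        df, y = cohort.data, cohort.y
        flagged = 0
        flagged_alone = 0
        for i in np.flatnonzero(y):
            q_pos = df["qsofa"].iloc[i] >= 2
            band_pos = (
                bv.assign_band(int(df["severity_score"].iloc[i]))
                >= Band.MODERATE
            )
            flagged_alone += q_pos
            flagged += q_pos or band_pos
        assert alone == pytest.approx(100 * flagged_alone / y.sum())
        assert combined == pytest.approx(100 * flagged / y.sum())

    def test_combined_never_below_qsofa_alone_any_cutoff(self):
        _, cohort = _generated_severity_cohort(n=5000, seed=8)
        for cutoff in bv.BANDS_ASCENDING:
            alone, combined = bv.combined_rule_sensitivity(cohort, cutoff)
            assert combined >= alone

    def test_cutoff_monotone_tradeoff(self):
        _, cohort = _generated_severity_cohort(n=5000, seed=8)
        sens, spec = [], []
        for cutoff in bv.BANDS_ASCENDING:
            sens.append(bv.combined_rule_sensitivity(cohort, cutoff)[1])
            spec.append(bv.combined_rule_specificity(cohort, cutoff)[1])
        # lowering the cutoff (earlier in the list) raises sensitivity,
        # lowers specificity
        assert sens == sorted(sens, reverse=True)
        assert spec == sorted(spec)

    def test_no_positives_rejected(self):
        df = make_patients()
        cohort = bv.build_cohort(df, "severity")
        with pytest.raises(ValueError, match="positive"):
            bv.combined_rule_sensitivity(cohort)


def hypergeom_enumeration_p(table):
    """Oracle: sum hypergeometric P of all tables at the observed margins
    with probability <= observed."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    from scipy.stats import hypergeom

    p_obs = hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = hypergeom.pmf(k, n, row1, col1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


class TestFisherExact:
    def test_no_association_gives_unity(self):
        assert bv.fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_perfect_association_matches_enumeration(self):
        p = bv.fisher_exact([[10, 0], [0, 10]])
        assert p == pytest.approx(1.083e-5, rel=1e-3)
        assert p == pytest.approx(
            hypergeom_enumeration_p([[10, 0], [0, 10]]), rel=1e-9
        )

    @given(
        a=st.integers(0, 15),
        b=st.integers(0, 15),
        c=st.integers(0, 15),
        d=st.integers(0, 15),
    )
    @settings(derandomize=True, max_examples=60)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        table = [[a, b], [c, d]]
        assert bv.fisher_exact(table) == pytest.approx(
            hypergeom_enumeration_p(table), rel=1e-9, abs=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            bv.fisher_exact([[1, -2], [3, 4]])
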