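"""Refine bedside qSOFA risk strata with the Severity score bands.

On a synthetic cohort: the 7-day ICU-level-care rate within the low
(qSOFA 0–1) and high (qSOFA 2–3) strata, further broken down by Severity
band, plus the sensitivity gain from flagging patients with qSOFA ≥ 2 OR
a Moderate-or-higher Severity band instead of qSOFA alone.
"""

import bandeval as bv

patients = bv.generate(bv.CohortSpec(n=30_000, seed=7))
cohort = bv.build_cohort(patients, "severity")

rates = bv.stratified_outcome_rates(cohort)
for name, stratum in rates.items():
    print(f"{name}: n={stratum.n}, ICU-level-care rate "
          f"{stratum.overall_rate:.1f}%")
    for band, cell in stratum.per_band.items():
        print(f"    {str(band):>9}: n={cell.n:6d}  rate {cell.rate:5.1f}%")

alone, combined = bv.combined_rule_sensitivity(cohort, bv.Band.MODERATE)
print(f"\nsensitivity for ICU-level care: qSOFA alone {alone:.1f}% → "
      f"qSOFA OR Severity ≥ Moderate {combined:.1f}%")
print("the combined rule can only add positives, so sensitivity rises; "
      "specificity pays for it.")
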