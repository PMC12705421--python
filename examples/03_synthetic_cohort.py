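"""Generate a synthetic cohort and check that it recovers its own design.

Draws 50,000 patients from the default generative model (calibrated to
the validation-study marginals), evaluates the bacterial axis, and
compares the empirical band likelihood ratios with the mass-ratio values
the model implies.  Agreement here is a consistency check of generator
plus evaluator, not evidence about real patients.
"""

import bandeval as bv

spec = bv.CohortSpec(n=50_000, seed=42)
patients = bv.generate(spec)
cohort = bv.build_cohort(patients, "bacterial", "consensus")
table = bv.build_band_contingency(cohort)

print(f"generated {spec.n} patients "
      f"(bacterial prevalence {spec.prevalence_bacterial:.1%})\n")
print(f"{'band':>10} {'empirical LR':>13} {'theoretical LR':>15}")
for band, theory in zip(bv.BANDS_ASCENDING, spec.implied_band_lrs("bacterial")):
    empirical = bv.band_likelihood_ratio(table, band)
    print(f"{str(band):>10} {empirical:13.3f} {theory:15.3f}")

print("\nempirical LRs track the band-mass ratios the generator was built "
      "on;\nsampling noise is largest in the sparsely populated extreme bands.")
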