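"""Post-test probabilities and antibiotic-treatment threshold crossings.

Applies odds-form Bayesian updating with the five bacterial band
likelihood ratios over a grid of pre-test probabilities, then asks at
which pre-test probability each band pushes the post-test probability
across the 69% treat threshold (rule-in bands) or keeps it below
(rule-out bands).
"""

import bandeval as bv

BAND_NAMES = ("Very Low", "Low", "Moderate", "High", "Very High")
BAND_LRS = (0.08, 0.54, 1.14, 2.50, 8.04)  # consensus bacterial bands

matrix = bv.post_test_matrix(BAND_LRS, band_names=BAND_NAMES)
print("post-test probability by pre-test probability and band:\n")
print(matrix.round(3).to_string())

policy = bv.ThresholdPolicy()  # 69% overall treat threshold
print(f"\ntreat threshold: {policy.treat_threshold:.0%}")
for name, lr in zip(BAND_NAMES, BAND_LRS):
    crossing = bv.threshold_crossing(lr, policy)
    if lr >= 1:
        print(f"  {name:>9} (LR {lr:5.2f}): crosses the threshold from "
              f"pre-test {crossing}")
    else:
        print(f"  {name:>9} (LR {lr:5.2f}): stays below the threshold up to "
              f"pre-test {crossing}")
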