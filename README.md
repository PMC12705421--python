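# bandeval

Band-stratified evaluation of multi-score host-response triage tests for
suspected acute infection and sepsis.

Emergency-department triage tests increasingly report not one number but
several: a score for the likelihood of bacterial infection, one for viral
infection, and one for the risk of decompensation (need for "ICU-level
care": mechanical ventilation, vasopressors and/or new renal replacement
therapy within 7 days). Each 0–50 score is read through five ordered
interpretation bands — Very Low, Low, Moderate, High, Very High — with the
extreme bands used clinically to rule out or rule in. `bandeval` is a
library for evaluating such a test from patient-level records: it builds
reference-standard cohorts from multi-reviewer adjudications, computes the
band-level accuracy machinery, and carries the results through to the
bedside questions (should this patient get antibiotics? does the score add
anything to qSOFA?).

## What it computes

For band *i* with `a_i` disease-positives and `b_i` negatives out of `P`
and `N` totals:

- **Stratum-specific likelihood ratio** `LR_i = (a_i/P) / (b_i/N)`, with
  log-normal or bootstrap CIs (80% by default), monotonicity and fold-range
  summaries.
- **Rule-in / rule-out accuracy**: rule-in bands report
  `sens = a_i/P`, `spec = 1 − b_i/N`; rule-out bands report
  `sens = 1 − a_i/P`, `spec = b_i/N`. Under the rule-in convention
  `LR_i = sens_i / (1 − spec_i)` exactly.
- **Band predictive value** `100·a_i/(a_i+b_i)` and relative frequency.
- **Bayesian updating**: `post = LR·pre / (LR·pre + 1 − pre)` over a
  pre-test grid, with treatment-threshold crossing analysis (69% treat
  threshold by default); at the cohort prevalence this reproduces the band
  predictive values exactly.
- **AUROC and DeLong's test** for paired score/biomarker comparison, plus
  stratified-bootstrap subgroup comparison.
- **Sequential qSOFA combination**: event rates per qSOFA stratum refined
  by Severity band; sensitivity of `qSOFA ≥ 2 OR band ≥ cutoff`; Fisher's
  exact test.
- **Clinical utility**: antibiotic over/under-treatment reclassification,
  a bacterial-sepsis surrogate cross-tab (Bacterial × Severity bands), and
  lactate gray-zone resolution.
- **Time-to-event by band**: Kaplan–Meier, log-rank and per-band Cox
  hazard ratios over the 7-day window (via lifelines).
- **Synthetic cohorts**: exact reconstruction of published band-count
  tables into patient-level cohorts, and a seeded parametric generator
  whose implied band LRs are known in closed form — real patient-level
  study data are protected, so all evaluation here runs on these.

## Worked example

Reconstruct the 729-patient consensus bacterial cohort from its printed
per-band counts and evaluate it
(`python examples/01_band_metrics_from_counts.py`):

```
consensus bacterial cohort: n=729, 460 infected / 269 not infected

     Band  Positive (N)  Negative (N) Sensitivity (%) Specificity (%) Likelihood ratio (CI) Relative frequency (% in band) Probability of infection (%)
Very High           165            12            35.9            95.5     8.04 (5.55–11.64)                           24.3                         93.2
     High           107            25            23.3            90.7      2.50 (1.92–3.27)                           18.1                         81.1
 Moderate            90            46            19.6            82.9      1.14 (0.93–1.41)                           18.7                         66.2
      Low            85            92            81.5            34.2      0.54 (0.46–0.64)                           24.3                           48
 Very Low            13            94            97.2            34.9      0.08 (0.06–0.12)                           14.7                         12.1

likelihood ratios span a 100.5-fold range across bands;
81.3% of patients fall in an actionable (rule-in or rule-out) band.
```

Reading the Very High row: a result there is 8× as likely in infected as
in uninfected patients, so at this cohort's 63.1% prevalence a Very High
result carries a 93.2% probability of bacterial infection — rule-in
territory — while Very Low results miss only 2.8% of infections (97.2%
rule-out sensitivity). The other examples walk through the Bayes
nomogram, the synthetic generator, qSOFA combination, clinical utility
and survival by band.

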