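# Methods

## Setting and data model

The package evaluates a three-score, five-band host-response triage test
for emergency-department patients with suspected acute infection or
sepsis. Each patient carries three integer scores in [0, 50] (Bacterial,
Viral, Severity), two four-level clinical adjudications (bacterial and
viral: Yes / Probable / Unlikely / No — no equivocal level exists),
day-of-onset fields for the ICU-level-care components (mechanical
ventilation, vasopressors, new renal replacement therapy), 28-day
mortality, qSOFA, ΔSOFA, laboratory covariates (lactate, CRP,
procalcitonin, WBC), a day-0 antibiotics flag and demographic fields. The
canonical container is a pandas DataFrame in a fixed CSV dialect (header
required, empty cells encode absent values).

Adjudication merging follows the two-reviewer + expert design: a
concordant axis stands; a discordant axis takes the expert's call; a
discordant axis without an expert is an error, and an expert supplied for
a concordant case is ignored with a warning. Expert calls may themselves
be Probable/Unlikely — the model does not restrict them to certain
levels. Two binary reference standards are derived per axis: *consensus*
(keep only Yes/No; Yes positive) and *forced* (keep everyone;
Yes∪Probable positive). A patient can be positive on both infection axes
(co-infection); axes are evaluated independently.

The severity endpoint is true iff any ICU-level-care component day is ≤ 7
(day 0 = presentation, inclusive — "within 7 days" is read as day ≤ 7 so
day-7 events are not undercounted). ICU admission alone never qualifies.
The composite endpoint adds death by day 28. A record with no qualifying
event is evaluable only if its follow-up covers the horizon; otherwise it
is excluded from severity cohorts with a logged count (the original
study's exact exclusion itemisation is not published, so the package logs
reasons rather than asserting a particular split).

## Interpretation bands

Scores map to Very Low (0–10), Low (11–20), Moderate (21–29), High
(30–39), Very High (40–50). Published sources state two boundary
conventions for the upper bands (21–29/30–39/40–50 in the quantitative
tables versus 21–30/31–40/41–50 in running text); the package adopts the
table convention as the quantitative source of record — all numerical
results here reproduce under it — and exposes the prose convention via a
`convention` flag. Very High and High are read as rule-in, Very Low and
Low as rule-out; Moderate uses rule-in-style formulas but is labelled not
actionable.

## Band metrics

With `a_i` positives and `b_i` negatives in band *i* (totals `P`, `N`):

- likelihood ratio `LR_i = (a_i/P)/(b_i/N)`; `+inf` when `b_i = 0 < a_i`,
  undefined (NaN, not zero) when the band is empty;
- rule-in bands: `sens = a_i/P`, `spec = 1 − b_i/N`; rule-out bands:
  `sens = 1 − a_i/P`, `spec = b_i/N`;
- band predictive value `100·a_i/(a_i+b_i)`; relative frequency
  `100·(a_i+b_i)/(P+N)`.

Internally everything is exact rational arithmetic (`fractions.Fraction`);
floats appear only at the reporting surface. Report rounding is half-up
(not banker's): 1 d.p. for percentages, 2 d.p. for likelihood ratios.
Two identities are maintained exactly and tested as such: under the
rule-in formulas `LR_i = sens_i/(1 − spec_i)`, and the odds-form Bayes
update at the cohort prevalence returns the band predictive value
(`pre/(1−pre)·LR_i` reduces to `a_i/b_i`).

LR confidence intervals default to 80% (z = Φ⁻¹(0.90) ≈ 1.2816), the
convention of the motivating study design. The log-normal interval is
`exp(ln LR ± z·sqrt(1/a − 1/P + 1/b − 1/N))`; a parametric bootstrap
(binomial resampling of band membership within each class, percentile
interval, seeded) covers zero cells. The CI method behind the originally
published interval bounds is not documented; this package reports its two
methods under their own names and does not claim to reproduce published
bounds (point estimates, sensitivities, specificities, frequencies and
predictive values all reproduce exactly).

Fold range (`max LR / min LR`) is computed by default on the
report-rounded 2 d.p. values, because that is the scale on which
"ranged over N-fold" claims are quoted (on the bacterial fixture the
rounded ratio is 8.04/0.08 = 100.5 while the exact ratio is 99.4); exact
values are available via `reported_rounding=False`.

## Bayesian updating and thresholds

`post = LR·pre/(LR·pre + 1 − pre)` on a pre-test grid of 0–1 in 0.1 steps
(endpoints included). Threshold crossings are reported on the grid — the
binned presentation a clinician would use — not by root-finding: rule-in
LRs report the smallest grid pre-test with post ≥ threshold, rule-out LRs
the largest grid pre-test kept strictly below it. Default thresholds come
from surveyed clinician decision points: 69% overall, 55% under high
illness severity, 84% under low severity. Crossings use band LR point
estimates, not CI bounds. Note that with LR 2.50 the post-test
probability at pre-test 0.5 is 0.714, so the High band's first grid
crossing of the 69% threshold is at 0.5 exactly.

## AUROC and DeLong comparison

AUROC is the Mann–Whitney estimator with mid-rank tie correction; its
variance and the paired two-score test use DeLong's structural
components (per-patient placement values), giving rank invariance under
monotone transforms. Degenerate zero-variance comparisons (identical
scores) return p = 1. Subgroup comparisons bootstrap within (group,
class) strata. Correctness is established against brute-force pair
counting (n ≤ 200) and a 10,000-replicate paired score-swap permutation
oracle rather than against published AUROCs: the published values (0.83
bacterial, 0.91 viral, 0.78 severity) require the unpublished continuous
score distributions, and band-reconstructed cohorts are band-resolution
only.

## Sequential qSOFA combination

Strata are qSOFA 0–1 versus 2–3. The combined rule is
`qSOFA ≥ 2 OR Severity band ≥ cutoff` with the cutoff an explicit,
required parameter defaulting to Moderate; the cutoff behind the
originally reported combined sensitivity is not published, so outputs
flag it as an assumption. Fisher's exact test (two-sided, hypergeometric
summation; scipy implementation, enumeration-oracle-tested) serves the
stratum comparisons.

## Clinical utility

Undertreated = adjudicated bacterial (consensus Yes) with no day-0
antibiotics, flagged when the Bacterial band is Moderate or higher;
overtreated = adjudicated non-bacterial (No) with day-0 antibiotics,
flagged when the band is Low or Very Low. Co-infected patients count as
bacterial-positive. The bacterial-sepsis surrogate is adjudicated
bacterial AND (ΔSOFA ≥ 2 OR ICU-level care within 7 days); a missing
ΔSOFA with a negative severity endpoint leaves the record undetermined
and out of cross-tab denominators. Lactate zones are < 2, [2, 4] and
> 4 mmol/l; the indeterminate zone is closed on both ends (the source
prose writes "2–4" without boundary semantics).

## Survival by band

Events are the earliest ICU-level-care component day; event-free patients
are administratively censored at day 7 (or earlier follow-up end).
Kaplan–Meier estimation, the log-rank test and Cox per-band hazard ratios
are delegated to lifelines; ties are handled by Efron's method (the
lifelines implementation; at least as accurate as Breslow for the heavily
tied day-resolution data here). A zero-event band is reported as HR 0
with a degenerate CI; a zero-event reference band triggers a
pooled-reference fallback (each band versus the rest) with a warning.
Whether death before intervention should be a competing event is not
resolvable from the published design; deaths without intervention are
censored.

## Synthetic cohorts

Real patient-level data are protected, so the package ships two
generators.

*Exact reconstruction* turns printed band-by-truth counts into
patient-level cohorts: each record draws a uniform integer score within
its band interval (the within-band distribution is unconstrained by the
published tables and irrelevant to band-level metrics), and severity
positives get a vasopressor day uniform on 0–7. Reconstruction is
bit-reproducible given a seed, and round-trips through the contingency
builder exactly.

*Parametric generation* draws from an explicit model whose defaults are
the study conditions: infection-status mix 448/165/12/104 out of 729
(bacterial-only / viral-only / co-infection / uninfected), severity
prevalence 122/1120, and per-class band masses equal to the published
contingency fractions, making the implied band LR `mass_pos/mass_neg`
exactly computable — the recovery oracle used in tests. Quantities the
published record does not constrain were fixed once at field-plausible
values and documented in the spec dataclass: qSOFA distributions per
severity class (high-qSOFA probability 0.60 in severe vs 0.15 in
non-severe courses), event days uniform on 0–7 with component mix
52/81/19% (ventilation/vasopressors/RRT, forced non-empty), 28-day
mortality 25%/2% by severity class, log-normal labs (e.g. lactate median
3.0 vs 1.4 mmol/l), ΔSOFA Poisson(3.0)/Poisson(0.6), and day-0
antibiotics rates rising with the Bacterial band within each adjudication
class. The two infection axes' band assignments are conditionally
independent given class — an assumption, since their joint distribution
is unpublished.

The prose-constrained utility fixtures pin only the published counts
(33 untreated-bacterial with 10/11/3 in Moderate/High/Very High; 103
treated-non-bacterial with 62 in Low∪Very Low; 213 indeterminate-lactate
patients with 58 severe, 46 flagged); within-band splits beyond those
counts are synthetic choices recorded in the fixture docstrings.

What passing tests show, and do not: the generator emulates schema,
marginal prevalences, band masses and coarse conditional structure. It
does not model gene expression, the classifier mapping expression to
scores, within-band score shape, site effects, seasonal case mix, or
correlated missingness — so generative-recovery tests validate the
estimators' correctness, not the test's real-world performance.

## Numerical and design choices

- Half-up decimal rounding at the reporting surface; exact fractions
  internally.
- All randomness flows through `numpy.random.default_rng` seeded per
  call; pipeline runs with the same config hash are byte-identical.
- Problem sizes in tests: generative checks run at n = 10⁵ for LR
  recovery (3-SE tolerances elsewhere at n = 2×10⁴–5×10⁴), hazard-ratio
  recovery at n = 2×10⁴, log-rank power at 100 seeded replicates of
  n = 2×10³ — sizes at which the sampling error of each check sits well
  inside its tolerance.
- The library-plus-examples surface is primary; the `bandeval` CLI is a
  thin argument-parsing layer over the same functions.

## Known limitations

- Published LR CI bounds and continuous-score AUROCs are not
  reproducible from printed information; the package makes no attempt to
  match them (see above).
- Band-reconstructed cohorts support band-level inference only.
- The clinical-utility analyses are reclassification counts, not causal
  or interventional estimates.
- No competing-risk handling in the survival module.
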