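# Methods

## Outcome and cohort

The unit of analysis is a patient observed over two consecutive calendar
years. The outcome is binary: *increase* iff total reimbursed costs in year
2 strictly exceed year 1 (`Δ > 0`); an exact tie counts as *decrease*, by
strict reading of the definition. Inclusion requires age ≥ 18, at least 5
prescriptions in each year, complete demographics and both annual totals.
Only year-1 information enters the features, so the model is usable
prospectively; the single year-2 quantity that appears anywhere
(next year's deductible band) is chosen by the patient before year 2 begins
and is treated as a self-assessment signal, not an outcome leak.

The 80/10/10 split is a uniform random permutation cut at `⌊0.8n⌋` and
`⌊0.1n⌋`; the remainder is the test set. At n = 373 264 this yields
298 611 / 37 326 / 37 327, which the test suite checks against the floor
rule.

## Features

Six named sets (the stepwise experiment adds them cumulatively):

| set | content | notes |
|---|---|---|
| demographic | 18 age bands, gender, language area, deductible bands (both years + changed flag), insurance model | all indicators; age bands are 5-year from 18, top band collapsed |
| counts | n hospitalisations, office visits, distinct ATC-5 drugs, prescription events | |
| chronic | distinct-code counts per ATC-prefix condition map | 6-condition stand-in map ships as default; the map is config |
| pharmacotherapy | prescription counts per 4th-level ATC class | vocabulary = classes observed in the *training* partition (no evaluation-time vocabulary leakage) |
| additional | monthly + quarterly histograms of office/bedside visits and prescriptions, weekend visits, length of stay, MDC / hospital-type / harm indicators, administration modes, dispensers, specialties, care events, interval statistics, distinct-ATC-4 and purchase-date counts | |
| costs | year-1 total costs | included only to assess complementarity |

Numerical conventions: no missing values anywhere — absent events are 0.
Interval statistics (median/mean/sd/min/max of gaps between successive
event dates, sd with n−1 denominator) are 0 for patients with fewer than
two events, with a companion `*_gap_has_intervals` indicator so that 0 is
unambiguous. Length of stay is discharge − admit in whole days (same-day
stay = 0). Two near-duplicate prescription-count conventions (event count
vs distinct purchase dates) are deliberately kept as distinct features.

## Models

`CostChangeModel(split, TrainConfig).fit()` returns a `CostChangeResults`.
Three families share one feature encoding:

* **LR** — scikit-learn logistic regression (L2, standardised inputs).
* **BDT** — xgboost, `binary:logistic`, histogram trees. Defaults:
  300 trees, depth 5, learning rate 0.1, `min_child_weight` 30,
  `colsample_bytree` 0.8, `base_score` 0.5. The last two regularisation
  choices were selected on the validation partition, which is that
  partition's purpose here. Column subsampling matters beyond accuracy:
  without it, one of several correlated markers of a latent group can
  monopolise every tree, and the others never appear on any decision path,
  which starves the interpretation layer. `base_score = 0.5` pins the
  margin intercept at logit(0.5) = 0, so "sum of scores positive ⇒
  increase" is literal.
* **FNN** — one hidden layer (width 64), standardised inputs; it
  participates in model comparison only, never in interpretation.

Accuracy is percent of samples with thresholded probability (> 0.5)
matching the label. AUC is the rank-based (Mann–Whitney) probability that a
random increase-patient outscores a random decrease-patient, ties ½.

## The neutral tree representation

Interpretation consumes a `TreeEnsemble` (base score in margin units; per
node: split feature, threshold, cover = training samples reaching the node,
leaf value), exported from the fitted booster's native JSON dump. Routing
is fixed as *left iff value < threshold*. Because feature matrices are
complete by construction, the representation has no missing-value default
direction, and importing a serialised ensemble that carries one is
rejected.

Floating-point fidelity: thresholds and leaf values are float32 in the
booster, so routing casts inputs to float32. Margins accumulate in float64
by default; accumulating in float32 instead reproduces the booster's raw
margins bit-for-bit (the booster sums in float32), and that is the mode
used when export fidelity is asserted. Attribution conservation is checked
against the ensemble's own float64 margin, where it holds to ≤ 1e-9 by
telescoping.

## Attribution (weight analysis)

Per-sample scores use cover-weighted path attribution: each node carries
the cover-weighted expectation of the leaf values below it; walking the
sample's root-to-leaf path, the split feature at each node receives
`E[child taken] − E[node]`. The intercept is the base score plus every
tree's root expectation. The decomposition sums exactly to the margin and
costs one tree traversal per sample — unlike Shapley-value attributions it
assigns interaction effects to the features actually split on, which is the
behaviour wanted when asking "which features did this model use for this
patient". A drug class *contributes to increase* on a sample when its score
is ≥ 5 % (configurable) of the sample's total positive score, analogously
for decrease; per-class reports give the count of contributing patients and
the share whose observed label matches the direction (label concordance,
not prediction concordance), decrease rows stratified by hospitalisation.

## Subgroup mining and gain

Every root-to-leaf path of every tree is a candidate rule. Paths are kept
when their constraints on the requested drug-class feature pin the
*prescribed* side — the merged interval requires count ≥ 1, i.e. its lower
bound is positive. A path's constraints merge into per-feature half-open
intervals `[lo, hi)`. Rules touching more than 5 distinct features are
discarded rather than truncated (truncation would change the conditional);
duplicates across trees are collapsed; support below 100 (configurable) is
dropped. For each rule, `gain = |P(increase | cut) − P(increase | cut
without the drug-class constraints)|`, with all constraints on the drug
feature removed together. An independent brute-force evaluator (test every
sample against every rule) verifies support, both conditionals and the
gain on small fixtures.

## Backward deletion

Greedy elimination over features: each round retrains once per candidate
with that feature removed, using a reduced booster (default 25 trees, depth
3) to keep the O(F²) loop affordable, deletes the feature whose removal
maximises validation accuracy (ties → lexicographic), then re-measures the
accepted deletion with a full refit; the loop stops when that full-refit
accuracy falls more than 0.5 accuracy points below the running best. At
desk scale (validation sets of 1–2 thousand) the tolerance is comparable to
the binomial noise of the accuracy estimate, so traces are short and
stochastic; the property that matters — informative features survive, noise
is deleted first, final accuracy stays within tolerance — is what the tests
assert.

## The synthetic cohort

The generator emulates the schema and the statistical structure of a large
two-year claims cohort; all randomness flows from one seed, and generation
is a pure function of the config. Demographic marginals (gender, language,
deductible bands, hospitalisation rate ≈ 17.8 %) and utilisation magnitudes
(≈ 19 prescriptions, ≈ 9 distinct drugs, ≈ 8 office visits per year,
log-normal costs with median ≈ CHF 3 900) target the cohort summaries of
large Swiss claims data; no claim of distributional fidelity beyond those
magnitudes is made.

Labels are drawn from an explicit per-stratum Bernoulli, so planted
conditional probabilities are exact:

* hospitalised (highest priority): P(increase) = 0.23; their year-1 costs
  are scaled up ×2.8, so the stratum also carries the regression-to-the-
  mean pattern in the cost columns;
* pregnancy-like (women < 35, not hospitalised, assigned w.p. 0.5):
  P = 0.85, marked by 2–3 folic-acid-analogue (`B03BB`) prescriptions,
  frequent magnesium co-medication, ≥ 5 gynaecology office visits in
  Q2–Q4 and at most one early-year visit;
* chronic-progressive (`N06DA`, 2–4 prescriptions): P = 0.80;
* acute-proxy (`N01AX`, intravenous): P = 0.25;
* residual: probability solved from the realised stratum counts so the
  cohort marginal hits the configured 0.52, then shifted within the stratum
  (centred, so the marginal is preserved) by a deductible self-assessment
  signal, a heavy-utilisation decrease, and a *discordant utilisation*
  interaction — many office visits XOR many prescriptions raises the
  increase probability. The interaction term is there by design: the
  model-family comparison is only informative if the data contain structure
  an additive model cannot represent, and each scenario class also mixes
  planted members with label-neutral background users so that conditional
  drug probabilities are non-degenerate.

Year-2 detail is generated only as aggregates (total costs consistent with
the drawn label, and a prescription count for the inclusion rule), because
the analysis uses year 2 solely for the label and inclusion.

What passing the recovery tests shows — and does not show: the pipeline
can, at n = 20 000, recover planted conditional probabilities, surface a
planted latent subgroup as a high-gain rule, and keep planted informative
features under backward deletion. It does not show that real claims data
contain such clean strata, nor that the attribution scheme matches any
causal notion of drug effect; conditional probabilities here are
descriptive, not causal.

## Problem sizes and seeds

The test suite and the acceptance script run cohorts of 20 000 patients
(single CPU, minutes in total); the recovery suite repeats the full
pipeline over 20 generator seeds. Reported split sizes at n = 373 264 come
from the split arithmetic alone, which is independent of cohort content.
All seeds are explicit (generator seed, split seed, training seed); two
runs with the same config are byte-identical, which the manifest checksums
in `run-all` make auditable.

## Known limitations

* The chronic-condition map is a 6-condition stand-in, configurable but not
  a validated clinical mapping.
* MDC codes, hospital types and insurance models are synthetic category
  sets, not any national catalogue.
* The attribution scheme is path-based, not interaction-exact; no
  significance testing is attached to gains or deletion decisions.
* The FNN is a minimal reference implementation, not a tuned architecture.
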