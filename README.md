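# claimscope

Year-over-year health-care cost-change classification on two-year insurance
claims data, with a boosted-decision-tree interpretation layer built for
pharmacoepidemiology: which drug classes, and which patient subgroups
defined by drug classes, drive predicted cost increases?

## The problem

Given one calendar year of claims for an adult cohort — prescriptions
(GTIN / 5th-level ATC codes, administration mode, dispenser), outpatient
office and bedside visits, DRG-coded hospitalisations, care events and
annual totals — predict whether each patient's total reimbursed costs will
*increase* in the following year (label: cost difference strictly > 0), and
explain the prediction. The package implements the full pipeline:

1. **Feature engineering** into six named sets: `demographic` (18 five-year
   age bands, gender, language area, deductible bands for both years,
   insurance model), `counts` (hospitalisations, office visits, distinct
   drugs, prescription events), `chronic` (ATC-prefix-derived chronic
   conditions), `pharmacotherapy` (prescription counts per 4th-level ATC
   class), `additional` (monthly/quarterly event histograms, weekend
   visits, hospital-stay descriptors, administration modes, specialties,
   care events, interval-regularity statistics), `costs` (year-1 total).
2. **Cohort construction**: inclusion (age ≥ 18, ≥ 5 prescriptions in each
   year, complete demographics), the binary label, and a uniformly random
   80/10/10 train/validation/test split (`⌊0.8n⌋ / ⌊0.1n⌋ /` remainder).
3. **Models**: L2 logistic regression, gradient-boosted trees (xgboost) and
   a one-hidden-layer feedforward network, organised as a Model/Results
   pair (`CostChangeModel(...).fit() -> CostChangeResults`), plus the
   stepwise feature-set experiment that adds one feature family at a time.
4. **Interpretation** of the boosted model through a neutral `TreeEnsemble`
   representation (routing rule: left iff `x < threshold`; prediction:
   increase iff `base_score + Σ leaf values > 0`):
   * *score attribution* — cover-weighted path decomposition of the margin
     into per-feature scores, exactly conservative
     (`intercept + Σ scores = margin`);
   * *weight analysis* — drug classes contributing ≥ 5 % of a sample's
     total positive or negative score, with the concordance of the
     contribution direction and the observed label;
   * *conditional drug probabilities* — P(increase | ≥ 1 prescription of a
     class), overall and stratified by hospitalisation (the overall value
     is the exact count-weighted stratum mixture);
   * *subgroup mining* — root-to-leaf decision paths that require a drug
     prescription are merged into interval rules (≤ 5 cuts), each scored by
     `gain = |P(increase | cut) − P(increase | cut without drug class)|`;
   * *backward deletion* — greedy feature elimination on validation
     accuracy with a 0.5-point tolerance.
5. **Synthetic cohort generator**: real claims of this kind are
   confidential, so the package ships a generator that emulates the schema
   and plants the structure the analysis relies on — regression to the mean
   after hospitalisation (P(increase | hospitalised) ≈ 0.23 vs ≈ 0.58
   without), a chronic-progressive drug class (anticholinesterase analogue
   `N06DA`, P ≈ 0.80), an acute-proxy intravenous class (`N01AX`,
   P ≈ 0.25), a pregnancy-like latent subgroup (women < 35, folic-acid
   analogue `B03BB`, repeated gynaecology visits, quiet first quarter,
   P ≈ 0.85), a deductible self-assessment signal, and a non-additive
   "discordant utilisation" interaction. Planted probabilities are exact by
   construction (per-stratum Bernoulli labels), so every interpretation
   procedure can be validated by parameter recovery.

## Worked example

```python
import claimscope as cs

bundle  = cs.generate(cs.GeneratorConfig(n_patients=20_000, seed=11))
split   = cs.build_labeled_split(bundle, list(cs.FEATURE_SETS), seed=7)
results = cs.CostChangeModel(split, cs.TrainConfig.bdt()).fit()
print(results.summary())
```

```
Cost-change classification results
==================================
model kind        : BDT
features          : 221 (additional, chronic, costs, counts, demographic, pharmacotherapy)
train/val/test n  : {'train': 16000, 'validation': 2000, 'test': 2000}
validation        : accuracy  63.1 %   AUC 0.682
test              : accuracy  63.9 %   AUC 0.682
```

The boosted model discriminates well above chance (the cohort's increase
share is ≈ 52 %). Interpretation recovers the planted structure:

```python
ens  = results.export_ensemble()
rows = cs.weight_analysis(ens, split)          # per-class contribution report
print(rows[rows.direction == "increase"].head(3).to_string(index=False))
```

```
 atc4 direction stratum    n       acc
N06DA  increase     all  140 77.142857
N01AX  increase     all 1224 59.313725
D15BC  increase     all   49 55.102041
```

The chronic-progressive class `N06DA` (planted P(increase) = 0.80)
contributes ≥ 5 % of the positive score for 140 test patients, 77 % of whom
really increased. Subgroup mining around the folic-acid analogue recovers
the pregnancy-like group (planted P = 0.85):

```python
rules = cs.mine_subgroups(ens, split, partition="train", atc4="B03BB")
print(rules[0].describe())
```

```
B03BB >= 2 AND age_73_77 < 1 AND deductible_changed < 1 AND weekend_visits >= 3  [n=235, P(increase|cut)=0.89, without B03BB: 0.52, gain=0.37]
```

A command-line interface mirrors the library
(`claimscope simulate | featurize | cohort | train | model-grid | interpret |
summarize | run-all`); `claimscope run-all --out reports/` drives the whole
pipeline and writes every report family plus a manifest of seeds and
checksums.

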