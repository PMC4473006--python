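# ostai

Osteoporosis pre-screening for postmenopausal women: the **OSTAi** index,
its derivation pipeline, and head-to-head diagnostic evaluation against the
NOF 2013 referral recommendation.

## The problem

BMD measurement by DXA is the diagnostic standard for osteoporosis
(T-score ≤ −2.5 at the lumbar spine, femoral neck, or total hip), but
scanning everyone is impractical. OSTA-style indices triage women for DXA
referral from two self-reported numbers. OSTAi, developed on a nationwide
Taiwanese survey of 12,175 postmenopausal women, is

```
raw   = 0.2 × (weight [kg] − age [years])
value = round(raw)            # nearest integer, ties away from zero
```

with risk categories **low** (value ≥ −1), **medium** (−4 < value < −1),
**high** (value ≤ −4), and a referral rule *value < −1*. On its development
cohort this gives sensitivity 73.1%, specificity 62.0%, PPV 57.5%, NPV
76.6%, and AUC 0.739 — beating the NOF 2013 rule set (refer all women ≥ 65,
younger women with BMI < 18.5 kg/m², prior fracture, glucocorticoid use, or
a bone-loss condition), whose specificity is only 46.7%.

The package is for epidemiologists and methodologists who want to (a) apply
the published score and comparator, (b) re-derive an OSTA-style index on
their own cohort — univariate screen at p < 0.05 → multivariable OLS of the
lowest-site T-score (per-10-unit coefficients) → integer index weights →
AUC-guided backward item reduction → Youden-optimal integer cutoff — or
(c) study the methodology itself on synthetic cohorts with known ground
truth.

## Worked example

```python
from ostai import (generate_cohort, apply_exclusions, derive_index,
                   evaluate_ostai, evaluate_nof2013, compare_rules)

cohort, truth = generate_cohort(n=12175, seed=42)   # study-like synthetic cohort
cohort = apply_exclusions(cohort)                   # QC: males/pre/missing/±3 SD
res = derive_index(cohort)                          # full pipeline
print(res.reduced_model.variables, res.reduced_model.weights, res.cutoff)

a, b = evaluate_ostai(cohort), evaluate_nof2013(cohort)
comp = compare_rules(a, b)                          # paired DeLong test
```

prints (seed 42):

```
('age', 'weight') {'age': -2, 'weight': 2} -2
OSTAi sens/spec: 72.2% / 57.5%
OSTAi AUC 0.710 (95% CI 0.701-0.720)
NOF AUC 0.604, diff 0.107, p=1.8e-137
```

Item reduction discards height, menopause age, and the binary factors
(each costs < 0.01 AUC) and lands on the published two-variable index with
weights −2 per 10 years of age and +2 per 10 kg of weight; the Youden
cutoff on a synthetic replicate comes out at −1 or −2, bracketing the
published −1. The equivalent CLI:

```
ostai simulate --n 12175 --seed 42 --output cohort.csv
ostai derive   --input cohort.csv --output model.json
ostai compare  --input cohort.csv --output comparison.json
ostai score    --age 70 --weight 45
  {"raw": -5.0, "value": -5, "category": "high", "positive": true}
ostai reproduce --fixtures published --output-dir out/   # published-count tables
```

`ostai reproduce` emits the full report bundle (site-combination counts,
regression coefficients + index weights, 2×2 tables with metrics, risk-band
prevalences, rule comparison) from a cohort CSV, a synthetic cohort, or the
published summary counts.

## Layout

- `ostai.cohort` — domain types, QC/exclusion rules, WHO case definition,
  site-combination bookkeeping
- `ostai.scoring` — OSTAi score/categories/decision, NOF 2013 rule
- `ostai.derivation` — screen, multivariable fit, integer weighting, item
  reduction, cutoff selection
- `ostai.evaluation` — confusion matrices, metrics, ROC/AUC with DeLong CIs,
  risk-band prevalence, paired rule comparison
- `ostai.simulate` — seeded synthetic cohort generator with ground truth
- `ostai.estimators` — scikit-learn-style wrappers (`IndexDeriver`,
  `OstaiScreen`, `Nof2013Screen`)
- `ostai.cli` — `ostai` command-line tool

See `docs/methods.md` for the statistical details and design choices.
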