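# pedtriage

Development and evaluation pipeline for a pediatric emergency-department
triage risk model, for biostatisticians and clinical-prediction researchers
working on admission-risk scores in low-resource settings.

At its core is a logistic model of hospital admission (a surrogate for
illness acuity) built from signs, symptoms and vital signs measurable at
first contact:

    logit(p) = β₀ + β₁·√age + β₂·HR + β₃·T + β₄·MUAC + β₅·VS(SpO₂)
             + β₆·concern + β₇·breathing + β₈·oedema + β₉·pallor

where age is in months, MUAC is mid-upper arm circumference (mm), and
VS(SpO₂) = 70.103·log₁₀(101.687 − SpO₂) − 55.833 re-expresses pulse-oximetry
saturation as the equivalent intrapulmonary shunt fraction. The package
provides:

- a seeded **synthetic cohort generator** with known ground truth (no data
  download required);
- **preprocessing**: composite outcome (admission ≥ 24 h or readmission
  within 48 h), median/mode imputation, the √age and virtual-shunt
  transforms, and an events-per-variable screen;
- **bootstrap-stepwise AIC consensus selection** (predictors kept when they
  appear in ≥ 80% of replicate stepwise models) and the final logistic fit;
- **evaluation**: pooled out-of-fold AUROC from stratified 10-fold CV,
  percentile bootstrap CIs, and bootstrap-bias-corrected calibration;
- **risk stratification** into non-urgent / priority / emergency at dual
  thresholds targeting ≥ 90% sensitivity (low) and ≥ 90% specificity (high);
- the published **nine-predictor score as a fixed function** with its 8%/40%
  category boundaries.

## Worked example

Score a single encounter with the published model:

```python
from pedtriage import triage_probability

p, category = triage_probability({
    "age_months": 9, "heart_rate_bpm": 180, "temperature_c": 39.5,
    "muac_mm": 120, "spo2_pct": 88, "parent_concern": 1,
    "difficulty_breathing": 1, "oedema": 0, "pallor": 1,
})
print(f"risk={p:.4f} category={category}")
```

prints

```
risk=0.9973 category=emergency
```

— a 9-month-old with tachycardia, high fever, low MUAC, desaturation and
three positive signs has a 99.7% predicted admission risk, far above the
0.40 emergency boundary. A well-appearing 12-month-old (HR 120, T 37.0 °C,
MUAC 140 mm, SpO₂ 98%, no signs) scores `risk=0.0255 category=non-urgent`,
below the 0.08 boundary.

Run the whole development pipeline on a generated cohort from the shell:

```bash
pedtriage run-all --out-dir out --seed 5 --n-bootstrap 200
```

which generates a 1,612-child cohort, derives the outcome (~23% positive),
selects predictors by bootstrap consensus, fits and cross-validates the
model, and writes `model.json`, `evaluation.json`, a three-category
stratification table and a manifest. Subcommands `generate`, `preprocess`,
`develop`, `evaluate`, `stratify`, `score` and `sample-size` expose the
individual stages; the library API mirrors them one-to-one.

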