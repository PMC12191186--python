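# fittriage

Threshold optimisation for quantitative faecal immunochemical testing (FIT)
as a triage tool in iron-deficiency anaemia (IDA).

## The problem

Patients investigated for IDA on an urgent cancer pathway usually undergo
both upper endoscopy and colonoscopy, yet the yield of significant colonic
pathology is low. Colon-capsule (or panenteric capsule) endoscopy is a less
invasive alternative — but a capsule examination that finds cancer, a large
polyp, or a high polyp burden must be *converted* to conventional
colonoscopy anyway, eroding the cost advantage. A FIT threshold can triage
patients: low-FIT patients go to capsule first, high-FIT patients straight
to colonoscopy. `fittriage` is a library for choosing that threshold.

Given a patient-level cohort (FIT in µg Hb/g faeces — possibly censored at
assay detection limits as `<7`, `<10`, `>400` — plus age, sex, haemoglobin
and colonic findings), the package:

1. **derives the urgent-conversion label** from findings under configurable
   referral criteria (default: CRC, any polyp ≥ 10 mm, or ≥ 3 polyps);
2. **quantifies FIT's discrimination** — ROC/AUC with DeLong 95% intervals,
   univariate and multivariable logistic odds ratios, paired AUC tests;
3. **locates candidate thresholds** three complementary ways:
   - a **CUSUM scan**: cumulative urgent conversions at or below each
     threshold in exact 0.1 µg/g steps; one-step jumps of ≥ 5 cases are
     inflection points, with conversion rates per threshold;
   - an **incremental significance scan**: logistic comparison of rising-FIT
     patients (10 < FIT ≤ t) against the low-FIT group (FIT ≤ 10) for each
     t, reporting the lowest persistently significant threshold;
   - **decision-curve analysis** (net benefit
     `NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)` against treat-all/treat-none,
     with each threshold probability mapped back to a FIT value through the
     fitted risk model) and an **adapted monetary analysis** pricing every
     confusion cell in GBP with the capsule at 83% of colonoscopy cost;
4. **simulates realistic cohorts** — censored log-normal FIT (median ≈ 16,
   mean ≈ 78 µg/g), logistic conversion risk, findings consistent with the
   drawn label — so the whole pipeline is testable without patient data.

## Worked example

```python
from fittriage import (SyntheticParams, generate_cohort, roc_with_ci,
                       cusum_scan, incremental_significance_scan)

cohort = generate_cohort(SyntheticParams(n=1531, seed=1))
roc = roc_with_ci(cohort.fit_values, cohort.urgent)
print(f"AUC {roc.auc:.3f} ({roc.ci_low:.3f}-{roc.ci_high:.3f})")
scan = cusum_scan(cohort)
print("jumps:", scan.jump_points)
sig = incremental_significance_scan(cohort)
print("first sustained threshold:", sig.first_sustained)
```

prints

```
AUC 0.739 (0.704-0.773)
jumps: [  7.  10. 400.]
first sustained threshold: 17.0
```

FIT discriminates urgent conversion moderately well (AUC 0.74). The jump
points at 7, 10 and 400 µg/g are the assay detection limits, where censoring
stacks many patients on a single value; the significance scan finds that the
excess conversion risk over the low-FIT group becomes persistently
significant from 17 µg/g upward in this simulated cohort. The scripts in
`examples/` walk through each capability (simulation, ROC accuracy,
threshold scans, decision/monetary curves, power, and the full pipeline) and
print a line explaining each number.

The full pipeline writes every table, summary and figure with a hashed JSON
index and is byte-reproducible from config + seed:

```python
from fittriage import RunConfig, run_full_analysis
index = run_full_analysis(RunConfig(synthetic=SyntheticParams(n=1531), seed=1,
                                    outdir="out", make_plots=True))
```

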