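# bamsa

Screening tools for obstructive sleep apnea (OSA) in male professional
drivers, and the machinery to evaluate them.

Undiagnosed OSA is a major risk factor for sleepiness-related traffic
accidents, and prevalences of 28–78% have been reported among truck
drivers.  Sending every driver to a sleep laboratory is infeasible, so
occupational health care needs a cheap questionnaire-based filter with
high sensitivity (miss few cases) and reasonable specificity (avoid
unnecessary polygraphy).  This package implements such a filter — the
five-item **BAMSA** score — together with the standard comparator
instruments and a complete diagnostic-accuracy toolkit, for
biostatisticians and occupational-health researchers who want to score
cohorts, evaluate cut-offs, audit published accuracy tables, or simulate
realistic driver cohorts.

## The instruments

**BAMSA** (0–5) adds one point for each of

| item | criterion |
|------|-----------|
| **B**MI      | > 30 kg/m² |
| **A**ge      | > 50 years |
| **M**ale     | male sex |
| **S**noring  | at least one night per week (BNSQ frequency ≥ 3) |
| **A**pneas   | witnessed breathing pauses at least sometimes (BNSQ response > 1) |

Both anthropometric thresholds are strict; snoring and apneas come from
the Basic Nordic Sleep Questionnaire's semi-quantitative 5-level
frequency scale rather than yes/no items.  Comparators: **STOP-BANG**
(0–8, original neck > 40 cm and updated sex-specific neck criteria),
**NoSAS** (0–17), the **Berlin** questionnaire (high/low risk from three
categories) and the **Epworth Sleepiness Scale** (0–24).  The reference
standard is the apnea–hypopnea index (AHI) from cardiorespiratory
polygraphy: AHI ≥ 5 (any OSA), ≥ 15 (moderate-severe), ≥ 30 (severe),
optionally combined with an abnormal maintenance-of-wakefulness test
(mean latency < 19.4 min).

For a test dichotomized at a cut-off the package reports sensitivity,
specificity, PPV, NPV with exact Clopper–Pearson 95% intervals, the
likelihood ratios LR+ = sens/(1−spec) and LR− = (1−sens)/spec, the
diagnostic odds ratio OR = LR+/LR− = (TP·TN)/(FP·FN), and the
dichotomized ROC area (sens+spec)/2.  For graded scores it computes the
tie-corrected rank AUC, P(S⁺>S⁻) + ½P(S⁺=S⁻), and compares paired AUCs
with the DeLong test (validated against `pROC::roc.test`), with a
stratified bootstrap as cross-check.

Two further components make published results auditable and the whole
pipeline testable:

* **reconstruct** — recovers the unique integer 2×2 table behind a
  printed accuracy row from (n, reference-positive count, rounded
  sensitivity and specificity), surfacing ambiguity instead of guessing,
  then re-derives every remaining printed statistic;
* **cohort** — a synthetic generator calibrated so that default cohorts
  of male drivers reproduce the study marginals (43.75% with AHI ≥ 5,
  17.5% ≥ 15, 7.5% ≥ 30, 43.75% habitual snorers, 16.9% never-snorers,
  a chance-level ESS, and MWT < 19.4 min in ≈ 20.5%).

## Worked example

```python
from bamsa import calibrate_defaults, evaluate, generate_cohort

cohort = generate_cohort(calibrate_defaults(n=160, seed=5))
report = evaluate(cohort, ["bamsa:5", "bamsa:4", "bamsa:3"], "AHI>=15")
print(report.formatted_frame().to_string(index=False))
```

prints (trimmed):

```
     label  TP  FP  FN  TN  SENS  SPEC   PPV   NPV  LR+    LR-   OR   ROC
bamsa >= 5   2   1  28 129  6.7% 99.2% 66.7% 82.2% 8.67  0.941 9.21 0.529
bamsa >= 4  17  11  13 119 56.7% 91.5% 60.7% 90.2%  6.7  0.473 14.1 0.741
bamsa >= 3  28  41   2  89 93.3% 68.5% 40.6% 97.8% 2.96 0.0974 30.4 0.809
```

Each row is one cut-off against moderate-severe OSA in one simulated
160-driver cohort: at cut-off 3 the score catches 28 of 30 cases (93.3%
sensitivity) at 68.5% specificity, while cut-off 4 trades sensitivity
for a 91.5% specificity — the screening trade-off the instrument is
designed around.  `report.overall_auc["bamsa"]` gives the multi-cutoff
AUC (0.867 here), and `report.delong` holds pairwise AUC comparisons
when several instruments are requested.

Auditing a published row takes one call:

```python
from bamsa import reconstruct_table, accuracy_metrics
t = reconstruct_table(n=160, n_pos=28, sens_printed="85.7", spec_printed="78.8")
# -> TP=24, FP=28, FN=4, TN=104; accuracy_metrics(t) then yields
#    PPV 46.2%, NPV 96.3%, LR+ 4.04, LR- 0.181, OR 22.3, ROC 0.823
```

The scripts in `examples/` each demonstrate one capability (scoring a
respondent, auditing all packaged published rows, simulating and
evaluating a cohort, DeLong comparisons across instruments).  A thin CLI
wraps the same functions:

```bash
bamsa simulate --n 160 --seed 5 --out cohort.csv
bamsa evaluate --cohort cohort.csv --endpoint "AHI>=15" --instrument bamsa:4
bamsa reconstruct --n 160 --n-pos 28 --sens 85.7 --spec 78.8
bamsa reproduce-tables --format markdown
```

## Layout

* `src/bamsa/instruments.py` — instrument scoring and calibration lines
* `src/bamsa/diagnostics.py` — 2×2 statistics, ROC/AUC, DeLong, bootstrap
* `src/bamsa/reconstruct.py` — 2×2 reconstruction and row verification
* `src/bamsa/cohort.py` — calibrated synthetic cohort generator
* `src/bamsa/pipeline.py` — endpoint evaluation and table reproduction
* `src/bamsa/cli.py` — command-line interface
* `docs/methods.md` — models, calibration and design notes
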