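# Methods

## Scope and data model

The unit of analysis is one male professional driver with questionnaire
data (BNSQ-style frequency items, Epworth items, pre-tallied Berlin
category items), measured anthropometrics (visit BMI, neck circumference),
and reference outcomes (AHI from cardiorespiratory polygraphy; optionally
the MWT mean sleep latency).  Measured BMI and neck values are
authoritative when both measured and self-reported values exist; the
printed calibration lines BMI(visit) = 2.36 + 0.913·BMI(questionnaire)
and NC(visit) = 18.47 + 0.548·NC(questionnaire) are provided for
converting self-reports when no measurement is available.  Missing
required fields raise errors rather than being imputed: the target
analysis is complete-case, and a silent zero would bias every score
downward.

## Instrument conventions

* BAMSA = [BMI > 30] + [age > 50] + [male] + [snoring ≥ 1 night/week] +
  [witnessed apneas at least sometimes].  Thresholds are strict:
  BMI = 30.0 or age = 50.0 score 0.
* BNSQ→binary mappings: response 3 on the 5-level frequency scale means
  "on 1–2 nights per week", so *snoring at least weekly* ⇔ freq ≥ 3,
  and *apneas at least sometimes* ⇔ any response above "never"
  (freq ≥ 2).  STOP-BANG's snoring/tiredness/observed-apnea yes/no items
  reuse the same mappings (tiredness ⇔ freq ≥ 3) so that one consistent
  dichotomization is applied across instruments; all of these live in
  `InstrumentConfig` and can be overridden.
* The updated STOP-BANG neck criteria are sex-specific; the exact
  published cut-offs are configurable, with defaults male > 43 cm /
  female > 41 cm.
* NoSAS uses the published weights (neck > 40 cm: +4; BMI 25–<30: +3,
  ≥ 30: +5; snorer: +2; age > 55: +4; male: +2; high risk ≥ 8); its
  "snorer" item defaults to the weekly-snoring mapping above.
* Berlin: categories 1/2 positive with ≥ 2 positive items (accepted
  pre-tallied), category 3 positive with hypertension or BMI > 30;
  high risk ⇔ ≥ 2 positive categories.

## Accuracy statistics

Positivity is score ≥ cut-off throughout, matching "BAMSA ≥ 4"-style row
labels.  From a 2×2 table: sens = TP/(TP+FN), spec = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN), LR+ = sens/(1−spec),
LR− = (1−sens)/spec, OR = LR+/LR−, dichotomized ROC area =
(sens+spec)/2.  Zero denominators yield *undefined* (`None`), never
infinities; a 100%-sensitivity row has LR− = 0 and an undefined OR,
matching the blank cell such rows print.  The OR is evaluated as the
integer cross-product (TP·TN)/(FP·FN) — algebraically identical to
LR+/LR− but exact in the cells, so decimal ties such as 528/128 = 4.125
format correctly.  Proportions carry two-sided exact Clopper–Pearson 95%
intervals (statsmodels `proportion_confint(method="beta")`); these are a
completeness feature, not part of the printed-table comparisons.

Formatting follows the printed convention: percentages rounded
half-away-from-zero to one decimal, ratios to three significant figures,
ROC areas to three decimals.  Half-away rounding is implemented with
`decimal` on the shortest round-tripping representation of the float,
because Python's built-in banker's rounding prints 4.125 as 4.12.

The graded-score AUC is the tie-corrected rank statistic
P(S⁺>S⁻) + ½P(S⁺=S⁻), computed from midranks; it equals the trapezoidal
area under the empirical ROC curve and is invariant under strictly
increasing score transforms.  Paired AUCs are compared with the DeLong
test: per-subject structural components V10/V01 from midranks, their
empirical covariance across classifiers, and a two-sided normal p-value
for the AUC difference.  The implementation reproduces
`pROC::roc.test(method="delong")` to four decimals on fixture data.  A
stratified bootstrap (cases and controls resampled separately, normal
approximation with the bootstrap SE of the paired difference) is
provided as an independent cross-check; at n = 20 the two agree to
within a few hundredths in p.

## Reconstruction of published rows

A printed accuracy row determines TP via
round(100·TP/n_pos, d) = printed sensitivity, and TN analogously, where
d is read off the printed cell ("97" → 0 decimals, "85.7" → 1).  The
search is exhaustive over 0..n_pos (0..n_neg), so it is deterministic
and order-independent; zero matches raise an inconsistency error and
two or more raise an ambiguity error carrying the candidates — ambiguity
is surfaced, never resolved silently.  For the packaged rows (28
accuracy-table rows over two endpoints plus the two MWT-combined rows)
every reconstruction is unique, and all 30 rows re-derive every printed
statistic exactly after rounding.  The packaged fixture keeps cells as
printed strings; a deliberately blank published cell (the undefined OR
of a 100%-sensitivity row) is encoded as `undef` and must re-derive as
undefined.  Overall multi-cutoff ROC areas of the source cohort are
*not* reconstructible from printed statistics — they depend on the
unpublished joint score/outcome distribution — and are covered only
qualitatively via the synthetic cohort (see below).

## Synthetic cohort model

The generator emulates the structure of a 160-driver male cohort; its
defaults are the study conditions, not tuning knobs.

* **Anthropometrics.**  Age ~ truncated normal(42.0, 9.3²) on [20, 58]
  years; BMI ~ truncated normal(28.3, 5.1²) on [19, 47] kg/m².  Neck
  circumference is normal around 41.2 cm (SD 3.1, clipped to [35, 52])
  with correlation 0.6 to BMI; waist is linear in BMI (mean 101.4 cm,
  SD 15.2, r = 0.85).  The source baseline table prints waist 41.2 cm /
  neck 101.4 cm, which is anatomically transposed; the generator uses
  the corrected assignment.
* **AHI.**  A latent liability L = 0.55·z(BMI) + 0.25·z(age) +
  0.30·z(neck) + 1.13·ε drives log-AHI.  With probability `p_low` a
  subject is a floor case (AHI ~ U[0, 2]); otherwise
  AHI = exp(μ + s·W), W the standardized liability, capped at
  120 events/h (≈ 0.7% of subjects, far above every analysis
  threshold).  The triple (p_low, μ, s) is solved by least squares
  against the empirical survival function of W on a fixed 200,000-draw
  reference sample — the same code path as generation, so truncation
  and clipping effects cancel — to satisfy the three exceedance
  constraints P(AHI ≥ 5) = 0.4375, P(AHI ≥ 15) = 0.175,
  P(AHI ≥ 30) = 0.075 (solution ≈ (0.120, 1.609, 1.300)).  The
  coefficient ratios encode BMI as the dominant anthropometric risk
  factor with smaller age and neck contributions; only their relative
  sizes matter, since the scale is absorbed by s.
* **Questionnaire items.**  Snoring and witnessed-apnea frequencies are
  drawn from 4×5 probability tables conditional on severity class
  (AHI < 5 / 5–15 / 15–30 / ≥ 30).  The tables were derived once, by
  hand, to satisfy the reported marginal and joint facts: habitual
  snoring 43.75%, snoring ≥ 3 nights/week 51.9%, never-snorers 16.9%,
  apneas ≥ sometimes 53.75%, nightly apneas 22.5%, P(AHI ≥ 5 | snoring
  ≥ 3/wk) ≈ 0.54, P(AHI ≥ 5 | never snore) ≈ 0.33 and P(AHI ≥ 15 |
  never snore) ≈ 0.074.  The severe-with-no-snoring corner has positive
  mass (P = 0.073 within the severe class), reflecting the reported
  severe non-snorer.  Snoring loudness is sampled conditional on
  frequency, with "very loud, intermittent" concentrated among frequent
  snorers.
* **ESS.**  A per-person propensity p ~ Beta(4.83, 8.50) with eight
  Binomial(3, p) items gives total mean ≈ 8.7 and SD ≈ 3.8 (the Beta
  overdispersion is solved from the two printed moments).  ESS is
  generated independent of AHI, so its AUC for any AHI endpoint
  converges to 0.5 — the study's central negative finding about
  subjective sleepiness as a screen.
* **Hypertension** ~ Bernoulli(0.169), independent of severity (a
  simplification; see limitations).
* **MWT.**  Latency ~ normal with class means (29.5, 26.5, 24.5, 23.0)
  min, SD 10, clipped to [0, 40]; this yields P(MWT < 19.4) ≈ 0.205
  and P(AHI ≥ 5 & MWT < 19.4) ≈ 0.122.  About 2.5% of latencies are
  missing, mirroring 156 of 160 completed tests; the combined endpoint
  is evaluated on complete cases.
* **Berlin counts** are Binomial with success probabilities increasing
  in snoring/apnea frequency (category 1) and tiredness (category 2);
  daytime-tiredness frequency has the fixed marginal
  (0.08, 0.09, 0.624, 0.13, 0.076), i.e. 83% tired ≥ 1 day/week and
  20.6% ≥ 3 days/week.

Randomness: one user seed feeds a `SeedSequence`; per-variable
sub-streams are spawned in a fixed order, so changing one structural
coefficient leaves all other variables' draws unchanged (common random
numbers).  This makes the generator deterministic given the seed and
gives clean stochastic-monotonicity behaviour: increasing the BMI
coefficient with everything else held fixed increases the dispersion of
the log-AHI predictor and hence mean AHI.

What the generator does **not** emulate: within-class dependence of
items beyond the class conditioning, hypertension–obesity correlation,
measurement error in AHI itself, or the exact joint distribution that
produced the study's overall AUCs (0.862 for moderate-severe OSA).  A
calibrated synthetic cohort gives BAMSA overall AUCs near 0.82–0.87 and
preserves the instrument ordering (BAMSA > STOP-BANG variants > NoSAS >
Berlin ≫ ESS), so passing tests demonstrate that the pipeline and the
qualitative structure are right — not that any real-data AUC is
reproduced to three decimals.

## Problem sizes and numerical choices

Statistical tests use one shared 100,000-subject default cohort
(generation ≈ 1.5 s); the coefficient-ablation oracle test and the
DeLong/bootstrap comparisons use 100,000 and 20 subjects with 10⁴
resamples respectively.  The exceedance solve uses
`scipy.optimize.least_squares` with tight tolerances on a piecewise
linear empirical survival function; residuals at the solution are
< 10⁻⁶.  Degenerate inputs are errors, not warnings: single-class
outcomes, unknown endpoints/instruments/variants, negative counts,
non-normalized item tables, and uncalibrated generator parameters all
raise typed exceptions.

## Known limitations

* Reconstruction requires the reference-positive count; rows whose
  printed marginals are ambiguous at the printed precision are reported
  as such and excluded from exact reproduction by design.
* The Berlin item battery is not administered; category 1/2 items enter
  pre-tallied.
* Predictive values are prevalence-dependent: synthetic-cohort PPV/NPV
  transfer only to populations with a similar ≈ 44% / 17.5% prevalence
  profile.
* All-male cohorts: female-specific behaviour of the instruments is out
  of scope (sex enters the scoring rules but the generator emits males
  only).
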