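# Methods

## The calibration problem

Accelerometers output dimensionless activity *counts* per epoch. Turning a
count stream into time spent sedentary or in light, moderate and vigorous
physical activity (LPA/MPA/VPA) requires *cut-points*: count thresholds
separating adjacent intensity bands. Published cut-points for children vary
several-fold, and a threshold calibrated on one population misclassifies
another. `cutcalib` implements a field-based calibration: a cohort wears
the device while a trained observer codes each 10-s interval with a SOFIT
physical-activity code (1 lying, 2 sitting, 3 standing, 4 walking, 5 very
active), and population-specific cut-points are derived by ROC analysis
against that direct-observation (DO) criterion.

## Data flow

1. **Epoch reintegration** (`align.merge_epochs`). Devices record 5-s
   epochs; these are merged to the 10-s observation grid by summing the
   constituent counts. Sum vs. mean differs only by a constant factor;
   because every threshold is expressed in counts·min⁻¹ via the
   ×(60/interval) rescale, the choice cannot affect derived cut-points. An
   incomplete trailing window is dropped and tallied, never padded.
2. **Alignment** (`align.align`). Each observation interval is joined to
   the 10-s epoch whose start time lies within ±1 s of the interval start.
   The tolerance is deliberately tight: devices and the observer's watch
   are synchronized before each session, so larger offsets indicate a data
   fault that should surface, not be absorbed. Unmatched intervals on
   either side are dropped pairwise and tallied; imputing counts or codes
   would contaminate the calibration. Two epochs matching one interval is
   treated as a clock fault and raises.
3. **Binarization** (`roc.binarize`). Per intensity class the codes become
   a binary criterion: sedentary ← {1,2}, moderate ← {4,5} (cumulative),
   vigorous ← {5}. The complementary codes are the negatives.
4. **ROC threshold search** (`roc.roc_curve`, `roc.optimal_cutpoint`).
   Candidate thresholds are the unique observed counts·min⁻¹ values plus a
   sentinel below the minimum, so both trivial operating points appear on
   the curve. The reported cut-point is therefore always an observed data
   value. Sedentary uses the `low_positive` rule (positive when cpm ≤ c) so
   the published "≤ cut-point" semantics hold without sign juggling;
   moderate and vigorous use `high_positive` (cpm > c).
5. **Cross-validation** (`crossval`). The cut-points are applied to
   held-out activities (DVD viewing, free-choice play — pooled, not
   stratified by activity) and summarized per class by a 2×2 contingency
   table (rows = DO criterion, columns = device classification),
   sensitivity, specificity, Cohen's κ and percent agreement, plus a
   ±90/±200 counts·min⁻¹ perturbation sweep around the moderate cut-point
   to show how robust the agreement is to cut-point error of the size
   debated in the literature.

## Statistical choices

**"Sensitivity and specificity both maximized"** is operationalized as the
Youden index J = sens + spec − 1, the standard optimal-threshold criterion
in clinical ROC software. Ties in J are broken toward the threshold with
the higher sensitivity (for `high_positive`, the lower threshold): a
calibration that misses activity is the costlier error in paediatric
surveillance. Among exact ties, observed values beat the sentinel endpoint.

**AUC** is computed as the Mann–Whitney pair statistic
(concordant + ½·tied)/(n₁·n₀) via midranks — the probability that a random
criterion-positive interval has more counts (or fewer, for the sedentary
direction) than a random criterion-negative one. A property test asserts
its exact equality with the trapezoidal integral of the empirical ROC
polygon. Ties contribute ½ to the AUC but are classified by the strict
≤/> rules at classification time.

**The AUC confidence interval** uses DeLong's structural-components
variance with a normal approximation, clipped to [0, 1]. Commercial ROC
packages report either DeLong or binomial-exact intervals without always
saying which; DeLong is chosen here as the non-parametric standard. A
perfectly separated sample has zero DeLong variance; the interval then
degenerates to a point and a warning is emitted rather than an error.
A test checks the interval against a 10,000-resample stratified bootstrap
on a small instance (agreement within 0.05).

**Cohen's κ** is computed from the 2×2 table margins,
κ = (p_o − p_e)/(1 − p_e). Zero-denominator ratios (a class absent from
the held-out data) are reported as explicit nulls with warnings, never
silently as 0 or 1.

**Pooling.** All participants' intervals are pooled with equal weight, with
no clustering adjustment — matching how field calibrations of this design
are analysed. A per-participant weighting could be added, but correlated
within-child intervals mainly affect the (reported, approximate) CI widths,
not the threshold point estimates.

**Ordering.** Derived cut-points must satisfy sedentary < moderate <
vigorous (light is the residual band). A violation raises an error advising
inspection of the data; silent reordering would mask an inverted or
hopelessly overlapped count distribution.

## The synthetic cohort

No public dataset pairs epoch counts with interval-level DO codes, so
`simulate` generates cohorts with the statistical structure the
calibration assumes:

* **Protocol menu** (defaults): drawing 10 min, DVD watching 10 min, brisk
  walking 5 min, jogging 5 min, playground games 10 min, free-choice games
  10 min; 28 participants. Drawing, walking, jogging and playground games
  are calibration activities; DVD and free-choice games are held out.
* **Codes**: one SOFIT code per 10-s interval from an activity-specific
  mixture with first-order persistence ρ = 0.5 (probability of repeating
  the previous code), giving the bouty, intermittent structure of
  children's activity without full semi-Markov machinery. Mixtures are
  what momentary time sampling plausibly records: drawing/DVD almost
  entirely sitting; walking dominated by code 4 with some standing;
  jogging nearly all code 5; the games a broad standing/walking/vigorous
  mix.
* **Counts**: cpm per interval from a code-conditional log-normal
  (counts are right-skewed), medians m₁ = m₂ = 50, m₃ = 700, m₄ = 3000,
  m₅ = 6500 cpm with log-scale σ = 0.45. These are configuration, not
  estimates: they place the class boundaries (midpoints 375/1850/4750 cpm)
  and the class overlap in the realistic range for waist-worn uniaxial
  devices in this age group, with the vigorous/moderate boundary the
  fuzziest — as in real calibrations. An optional point mass at a low
  count models zero-inflated still sitting (off by default).
* **Device stream**: the 10-s count is round(cpm/6), split into two 5-s
  epochs by symmetric binomial thinning, so the simulator exercises the
  same reintegration path as real 5-s exports.

The generator's *ground truth* — the boundary midway between adjacent code
medians — supports parameter-recovery tests: across 100 seeded cohorts the
derived cut-point must fall between the flanking code medians for every
class in ≥95 runs. What passing these tests shows: the pipeline recovers
the thresholds implied by its own generative assumptions, at the study's
sample size, under realistic overlap. What it does not show: robustness to
device saturation, non-stationary wear, observer error correlated with
counts, or between-child count heterogeneity — none of which the simulator
models.

## Numerical details and degenerate inputs

* Thresholds, sensitivities and specificities are exact ratios of counts;
  tie comparisons in the Youden scan use a 1e-12 absolute guard.
* Single-class inputs (e.g. an all-sedentary session) raise "degenerate
  ROC" rather than returning an arbitrary threshold.
* Timestamps are ISO-8601 in files, seconds internally; grids are
  validated to 1 µs.
* All randomness flows from one integer seed through
  `numpy.random.SeedSequence.spawn`, so cohorts are reproducible and
  participant streams independent.
* Reports round only at serialization (percent to 1 decimal, κ to 2, AUC
  to 3); full precision is kept internally.

## Problem sizes

The default cohort is 28 participants × 50 min = 8 400 aligned intervals
(5 040 calibration, 3 360 held-out); one simulate-calibrate-validate cycle
takes well under a second, and the seed-sweep tests (100 cohorts) run in
tens of seconds.

## Known limitations

* Uniaxial counts only; no vector-magnitude, heart-rate or energy-
  expenditure anchoring (the protocol is DO-criterion-referenced by
  design).
* Pooled analysis ignores within-child correlation (see above).
* The DeLong CI assumes independent intervals; with bouty data it is
  anti-conservative.
* CSV is the only interchange format; proprietary device containers must
  be exported to CSV first.
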