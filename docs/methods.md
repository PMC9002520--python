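# Methods

This note documents the statistical procedures, the synthetic data
model, and the design decisions behind `sleepvalid`. Everything stated
here is computed by the package; numerical claims are reproduced by the
test suite or the analysis scripts.

## The validation problem

A contactless sleep tracker reports, per 30 s epoch, heart rate (HR),
breathing rate (BR), a continuous sleep score and a binary sleep/wake
call. Polysomnography (PSG) provides the reference: scored sleep stages
(W, N1, N2, N3, REM), ECG-derived HR and flow-derived BR. Validation
proceeds on three levels: epoch-by-epoch vitals agreement, epoch-by-epoch
sleep/wake classification, and all-night summary variables (SOL, WASO,
TST, SE). Throughout, differences are oriented **reference − device**,
so a positive bias means the device underestimates.

## Clock alignment

Device and PSG run on independent clocks. Large body movements are
visible in both systems, so the residual offset is estimated as the
integer epoch lag maximizing the normalized cross-correlation of the two
movement channels over ±`max_lag` (default 20 epochs = 10 min), ties
broken toward the smallest |lag| then toward the negative lag. Positive
lag means the device clock runs behind; the estimated lag is removed
from every device stream before any comparison. The estimator recovers
every |lag| ≤ 20 exactly on noiseless data (tested exhaustively). Only a
single global lag is estimated; within-night drift re-estimation is out
of scope (the generator's default drift is zero).

## Curation

Epochs with reference artifacts are excluded first; among the remainder,
epochs without a device reading count as "not covered" and define the
coverage rate. The tallies satisfy
`artifact_excluded + not_covered + analyzed = total` on every input.
Device-uncovered HR epochs are *not* excluded from the sleep/wake
classification stream by default — the classifier always emits a state —
but `align_subject(exclude_uncovered_from_classification=True)` flips
that policy. Artifact masks apply only to the signal they annotate.

## Bland–Altman battery

* **Single measurement per subject** (`simple_ba`): bias = mean
  difference, LOA = bias ± 1.96 s (sample SD), CI(bias) = bias ±
  t·s/√n, CI(LOA) = LOA ± t·s·√(3/n), t = t(0.975, n−1).
* **Repeated measures** (`rm_ba`): one-way random-effects ANOVA with
  subject as factor. σ̂²_w = MSW; σ̂²_b = max(0, (MSB − MSW)/n₀) with
  n₀ = (N − Σnᵢ²/N)/(m−1); LOA = bias ± 1.96·√(σ̂²_b + σ̂²_w). The bias
  CI uses Var(bias) = (σ̂²_b·Σnᵢ² + σ̂²_w·N)/N² on t(m−1) — exact for
  balanced designs, where the simulated coverage of an injected bias is
  93–97 % over 500 replicates. LOA CIs add the delta-method variance of
  the total SD, treating MSB and MSW as independent scaled chi-squares:
  Var(σ̂²) = 2MSB²/((m−1)n₀²) + (1−1/n₀)²·2MSW²/(N−m),
  Var(σ̂) = Var(σ̂²)/(4σ̂²). The variance decomposition matches a REML
  fit to within 2 % on balanced instances away from the σ²_b = 0
  boundary; on unbalanced instances the method-of-moments and REML
  estimators legitimately differ by more.
* **Gates**: Shapiro–Wilk on the differences (a seeded 5 000-epoch
  subsample when larger — at such n the test flags trivial departures
  anyway); OLS of differences on the reference (proportional bias); OLS
  of |bias-model residuals| on the reference (heteroscedasticity). All
  gates two-sided at α = 0.05 (configurable).
* **Modeled path**: if any gate fires, bias and LOA become functions of
  the reference: bias = b₀ + b₁·ref (b₁ = 0 when proportional bias is
  not detected) and LOA half-width = 2.46·(c₀ + c₁·ref). Since
  E|e| = σ√(2/π) for centered normal errors, 2.46·E|e| ≈ 1.96σ, which
  the tests verify to 5 %. Coefficient CIs come from the basic
  (reflected-percentile) bootstrap with B = 1000, resampling whole
  subjects, so epoch-level autocorrelation within a subject does not
  invalidate them.
* **Log path**: non-normal differences from nonnegative measurements are
  retested on the ln(x+1) scale (the +1 admits zero SOL); the transform
  and both p-values are recorded. The reported model coefficients stay
  on the original measurement scale so they can be read against the
  measurements directly — a deliberate choice, since the regressor is
  the reference value either way and a back-transformed band is harder
  to audit. The regressor is always the reference, never the device.

The decision tree emits the plain result only when all three gates are
negative; the choice between `simple_ba` and `rm_ba` follows the mode
(summary vs epoch). With fewer than 4 pairs the gates cannot run and the
plain result is returned directly.

## Classification metrics

Sleep is the positive class. Besides the standard 2×2 rates, two
imbalance-aware statistics are reported, because overnight data are
roughly three-quarters sleep: PABAK = 2·accuracy − 1 (the
prevalence-and-bias-adjusted kappa for a 2×2 table — the identity is
asserted exactly on random tables) and d′ = Φ⁻¹(sens) − Φ⁻¹(1 − spec)
with rates clamped to [1/(2N), 1 − 1/(2N)] of the relevant truth class
so perfect rates stay finite (the clamping rule is this package's
choice). Cohort summaries are unweighted means ± SD across subjects,
with undefined (single-class) values dropped and counted. The ROC is
pooled over all subjects' epochs — one study-level curve matching the
single reported AUC — via a threshold sweep whose trapezoidal area
equals Mann–Whitney pair counting with ties at half weight (cross-checked
against brute-force enumeration and scikit-learn).

## Summary variables

From the consensus hypnogram (per-epoch majority of three scorers,
expert adjudicating three-way ties): SOL = minutes from lights-off to
the first non-wake epoch; WASO = wake minutes strictly between sleep
onset and the last non-wake epoch (sleep offset — defined here as the
last non-wake epoch, so terminal wake is reported separately and the
partition SOL + WASO + TST + terminal wake = TIB is exact); TST = 0.5 ×
non-wake epoch count; SE = TST/TIB. Minutes are epochs × 0.5 with no
rounding; an all-wake night has SOL = TIB. Device summaries use the same
definitions on the predicted sleep/wake series with the reference
lights-off/on window (the device's own bed-detection boundary is not
modeled).

## Concordance

Per subject, the device and reference HR (and BR) profiles are smoothed
with a centered 15 min moving average that ignores masked epochs
(renormalizing rather than interpolating, to avoid inventing data at
coverage gaps) and correlated at lag zero; the p-value uses the t
distribution on n−2 df, which ignores residual autocorrelation after
smoothing and is therefore anti-conservative — flagged, not resolved.
Lag zero is used because clock alignment has already been applied.
Cohort level: unweighted mean ± SD, a two-sided paired t-test for HR vs
BR, and OLS of HR concordance on sex (female = 1), age and BMI. AHI is
accepted as an optional covariate but excluded from the default
three-covariate model. The sample-size calculator returns the smallest
n ≥ 4 whose back-transformed Fisher-z 95 % CI at the anticipated r has
total width ≤ 2 × half-width; "CI width 0.1" is read as half-width ±0.1,
the reading under which the calculator reproduces the planning value
n = 36 at r = 0.85.

## Synthetic cohort model

The generator's defaults define the study conditions; they are
calibrated once to a typical adult laboratory cohort and are not tuned
per experiment.

* **Hypnogram**: first-order Markov chain on the five stages at 30 s
  resolution — the minimal process with realistic bout structure. The
  night starts awake; sleep onset is drawn from a lognormal with mean
  16.4 and SD 13.6 min (parameterized by distribution mean/SD), the
  onset stage from {N1 0.70, N2 0.28, REM 0.02}; thereafter the default
  transition matrix (long-run mix ≈ 0.12 W / 0.05 N1 / 0.50 N2 /
  0.20 N3 / 0.13 REM after onset, wake bouts ≈ 2.5 min) governs the
  chain. Time in bed is drawn per subject from N(918, 55²) epochs
  clipped to [686, 1036]. Simulated cohorts average TST ≈ 389 min,
  WASO ≈ 54 min, SE ≈ 0.85. A wake row without sleep mass (absorbing
  wake) yields an all-wake night.
* **Vitals**: instantaneous HR/BR at 60 samples per epoch (raw
  device-level sampling is out of scope; only epoch means matter
  downstream): stage baseline + a mid-night sinusoidal dip (2 bpm HR,
  0.3 BR) + AR(1) noise (φ = 0.97), floored at 1. Stage baselines
  (HR 72.9/69.4/67.4/64.4/70.4; BR 16.2/15.6/15.2/14.7/15.7 for
  W/N1/N2/N3/REM) put the pooled overnight means at ≈ 66.4 bpm and
  ≈ 14.9 breaths/min; between-subject level offsets are N(0, 9²) bpm
  and N(0, 2²) breaths/min.
* **Device**: value = ref − constant bias − proportional bias·ref +
  N(0, c₀ + c₁·ref); defaults HR bias 0.23 bpm / noise 3.2 bpm,
  BR bias 0.08 / noise 1.05, coverage 93.6 % / 99.4 %, clock offset
  60 s (2 epochs). The sleep score is logistic(logit(p_state) + AR(1)
  noise) with p = 0.90 in sleep and 0.52 in wake and marginal noise SD
  1.41, thresholded at 0.5 — chosen so that per-subject sensitivity ≈
  0.94 and specificity ≈ 0.48; the AR coefficient 0.75 makes
  predictions form runs rather than flicker (any monotone score with
  tunable operating point suffices for ROC work — the score model does
  not imitate any particular classifier). Movement bursts appear at
  wake-bout onsets in both systems' channels, which is what makes the
  alignment estimator work.
* **Scorers**: each of three technicians reproduces the true stage with
  probability 0.9, otherwise errs uniformly over the other four stages;
  the expert is error-free. PSG artifacts hit 1 % of epochs (one shared
  mask for HR and BR, matching the single artifact column in the
  serialized format).
* **Covariates**: age N(41.2, 10.5²) clipped to [22, 64]; 55.6 % female;
  BMI N(25.9, 4.4²); AHI lognormal(0.75, 1.5) (mean ≈ 6.5 events/h, a
  covariate only — apnea events themselves are not simulated). BMI and
  sex couple into the device HR noise intercept (+0.15 bpm per kg/m²
  above the mean, +0.8 bpm for women, floored at zero), so HR
  concordance declines with BMI and is lower in women.
* **Seeds**: subject i uses `default_rng(master_seed + i)`; identical
  (config, seed) reproduce cohorts bit for bit.

### What the generator does and does not emulate

It reproduces the statistical *structure* the analysis assumes —
stage-dependent vitals, heteroscedastic device error, coverage gaps,
clock offset, scorer disagreement, covariate-coupled noise. It does not
reproduce every empirical magnitude of a real study: smoothed-profile
concordance comes out higher than typical field values (no sensor drift
or posture-dependent nonstationarity is modeled), and the device's
epoch-level sleep/wake calls, lacking a real classifier's temporal
priors, drive device SOL toward zero (about half of wake epochs are
called sleep, so the first predicted-sleep epoch arrives within a couple
of minutes). Passing tests therefore demonstrate that the *pipeline*
recovers injected truth under realistic structure, not that any
particular device meets these numbers. The known inconsistency between a
pooled sleep prevalence of ~74 % and a mean SE of ~87 % in published
cohort tables is left as two independent knobs (chain calibration vs
score prevalence); the default chain follows the sleep-architecture
targets, and the classification stream simply reports its own
prevalence.

## Numerical choices and degenerate inputs

Ties in the lag scan break toward small then negative lags; identical
differences short-circuit the agreement tree to an exact plain result;
Shapiro–Wilk outside 3 ≤ n ≤ 5000 raises rather than silently degrading;
Pearson r within 1e−12 of ±1 reports the degenerate CI (r, r);
bootstrap distributions with zero range return a degenerate interval
with a warning; rank-deficient covariate designs raise naming the
constant columns; subjects with a single epoch difference trigger a
logged fallback from the repeated-measures to the single-measurement
formulas. Analysis problem sizes (45 subjects, ~900 epochs each, B =
1000 bootstrap, 50 000-epoch ROC experiments) keep every script and the
full test suite in the seconds-to-a-few-minutes range on one CPU.

## Known limitations

Single global clock lag (no drift correction within a night);
t-distribution p-values on smoothed profiles; no multi-stage (5-class)
agreement; no apnea/periodic-limb-movement event simulation; no raw
waveform synthesis; mixed-model or percentile LOA schools and
equivalence testing are out of scope.
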