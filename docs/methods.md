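# Methods

This note documents the models and procedures implemented in `sleepsense`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## Problem setting

A participant wears a wrist device (Empatica-E4 class) from at least four
hours before bed until at least four hours after waking, and each morning
rates their perceived sleep quality on a 1–5 Likert scale.  The device
records blood volume pulse (BVP, 64 Hz), electrodermal activity (EDA, 4 Hz),
3-axis acceleration (32 Hz) and skin temperature (4 Hz).  The pipeline
reduces each night to 52 interpretable features, labels the night as
high/low sleep quality, and evaluates explainable classifiers under repeated
leave-one-participant-out cross-validation (LOSO-CV).

## Feature extraction

### Cardiac (24 features)

Beats come from one of two sources, which define the two dataset variants:

* **Variant A (device condition)** — the watch's own inter-beat intervals
  (IBIs).  The device drops segments it believes are motion artifacts, so
  the series contains discontinuities: a beat is *contiguous* only when its
  offset gap matches its stated IBI (10 ms slack for file rounding).
* **Variant B (processed condition)** — beats detected from the raw BVP.
  The signal is band-passed with a 4th-order Chebyshev type II filter,
  zero-phase (forward–backward) so peak timing is unbiased.  Chebyshev II
  filters are parameterized by stopband edges; these sit at half the lower
  and 1.3× the upper cutoff (0.5 / 10 Hz), chosen so a 1.2 Hz pulse passes
  with ≥ 0.9 gain while drift below 0.05 Hz and noise above 25 Hz are
  attenuated by more than 20 dB.  The mean is subtracted before filtering
  because the Chebyshev II stopband floor is equiripple, not zero.
  Systolic peaks are local maxima above a 0.75 s rolling-mean threshold
  (raised by half the signal's median absolute deviation), with a 300 ms
  refractory period and parabolic sub-sample refinement.

IBIs are windowed into 5-minute windows stepped by 2.5 minutes.  A window is
kept only when its summed IBIs cover ≥ 95% of it (beats never tile a window
exactly) and, in the device condition, every beat is contiguous — one
missing beat drops the window; nothing is ever interpolated.  In the
processed condition a quality gate drops the window when more than 10% of
beats are rhythm outliers (deviation > 30% from the 11-beat local median) or
more than 5% of IBIs are implausible (< 300 or > 2000 ms).  Pure noise fails
this gate essentially always.

Per kept window: HR = 60000 / mean(IBI); RMSSD = √mean(ΔIBI²); SDNN =
population SD of IBIs; SD2 = √max(0, 2·SDNN² − SDSD²/2), the Poincaré-plot
long axis, with SDSD the population SD of successive differences.  All SDs
use the population (÷N) convention so that oracle tests have a fixed target.
Features are mean/max/min of each metric per phase (awake/asleep): 24
values.

HRV metrics can additionally be adjusted for gender, age and time of day by
a stratified z-score (strata: gender × age decade × 3-hour bin; strata under
10 windows fall back to pooled statistics).  HR is left raw — the adjustment
targets HRV only.  The adjustment reference is refit inside each training
fold when window-level data is supplied to `loso_cv`; the default feature
table carries unadjusted metrics, since per-participant normalization
already absorbs any participant-constant stratum shift and is leakage-safe
by construction.

### Electrodermal activity (12 features)

Three per-second validity rules, applied in order on 1-second blocks aligned
to the recording start: (1) samples below 0.05 µS imply lost skin contact;
(2) a second whose amplitude changes by ≤ 0.01 µS implies the sensor did not
measure; (3) skin conductance can change physiologically by at most +20% /
−10% per second, so a 1-second step outside [0.9x, 1.2x] of the starting
amplitude x is an artifact.  The rules are stated per second; the block grid
is this package's resolution choice.  Features are level mean/max/min over
valid samples and least-squares slopes over the 5-min/2.5-min window grid
(windows under 50% valid are skipped), per phase.  The 5-minute slope
scheme matches the temperature channel for consistency; OLS is preferred to
first differences for robustness at 4 Hz.

### Actigraphy (4 features)

Activity counts: per-axis 4th-order Butterworth high-pass at 0.25 Hz
(removes gravity and posture), per-second maximum absolute deviation across
axes (g), summed per 60-second epoch and scaled by 100 (floored).  The
count recipe is calibrated so that restful epochs score asleep under both
published scoring rules with their original thresholds:

* Sadeh: PS = 7.601 − 0.065·MW5 − 1.08·NAT − 0.056·SD6 − 0.703·ln(act+1),
  sleep iff PS ≥ 0 (MW5: mean count in the centered 11-epoch window; NAT:
  epochs in that window with counts in [50, 100); SD6: SD of the trailing 6
  epochs).  Boundary epochs use truncated windows.
* Cole-Kripke (1-minute epochs): D = 0.001·(106·A₋₄ + 54·A₋₃ + 58·A₋₂ +
  76·A₋₁ + 230·A₀ + 74·A₊₁ + 67·A₊₂), sleep iff D < 1; out-of-range
  neighbors count as zero activity.  Rescoring rules are out of scope.

Sleep onset is the start of the first run of ≥ 10 consecutive sleep-scored
epochs at/after the reported bedtime; wake is the end of the last such run
ending within ±30 minutes of the reported wake time ("a one-hour window
around").  Onset and wake are each averaged over the two algorithms'
timestamps — averaging results, not per-epoch votes.  Latency = onset −
bedtime; duration = wake − onset.  Features: duration, latency, and summed
counts per phase.

### Temperature (12 features)

Level mean/max/min on the raw 4 Hz signal and OLS slopes on the
5-min/2.5-min grid (°C/min), per phase, windows assigned by midpoint.

## Dataset construction

The asleep phase is the half-open [onset, wake); the awake phase is all
in-session time outside the sleep period within the 24 hours preceding wake
(this resolves the ambiguity between evening-only and full-previous-day
wear; the post-wake morning belongs to the *next* night's day).  A night
missing any feature — including nights whose sleep period cannot be
estimated — is removed, never imputed; participants left with no nights
leave the roster.

Two labelings: *absolute* (high iff response ≥ 4) and *normalized* (features
z-scored within participant, population SD; high iff the response is at
least the participant's own mean — "at least as well as their personal
average").  A zero-SD feature within a participant normalizes to 0, keeping
the observation.  Normalization requires ≥ 2 nights and ≥ 2 unique
responses per participant; others are excluded with a warning.

Diagnostics: the label-balance report gives the proportion of the
under-represented binary label per participant (≤ 0.5 by construction), and
the variance decomposition compares the SD of per-participant means
(between) with the mean of per-participant SDs (within).

## Models and evaluation

Three families, all emitting P(high): a bagged randomized-tree ensemble
(random-forest style; 500 trees, depth cap 6, √p feature subsampling), an
unpenalized logistic regression (GLM), and a logistic additive model (GAM)
with 10 cubic B-spline basis functions per feature and a second-order
(curvature) penalty, fit by penalized IRLS.  When the spline basis dimension
reaches 80% of the training size the IRLS fit separates perfectly and is
ill-posed; the same additive basis is then fit with a ridge-penalized
logistic regression instead.  Actigraphy features enter every model; the
ablation grid spans the 8 subsets of {cardiac, temperature, EDA}.

LOSO-CV holds out one participant per split and repeats the full cycle 10
times (150 splits at 15 participants).  Train and test sets are balanced
independently by randomly downsampling the over-represented class, seeded
per (seed, repeat, participant), so metrics are computed on perfectly
balanced test sets — balanced accuracy equals plain accuracy there, and
micro-F1 (global-count F1) equals accuracy in the binary case.  AUC uses
the rank statistic with mid-ranked ties.  Under normalized labeling the
per-participant statistics are computed inside the training fold for
training participants and from the held-out participant's own nights alone,
so no held-out information reaches training.

## Interpretation

Partial dependence: PD(v) = mean over observations of P(high | feature := v,
others fixed), on a 20-point grid between the 5th and 95th percentiles
(robust to outliers), centered to mean 0 over the grid.  Stability comes
from 100 bootstrap refits (resample observations with replacement, balance,
refit); each refit's PDP is evaluated on the full data, with an optional
seeded cap on the number of background rows for large panels.  Feature
importance — the average change in predicted probability attributable to a
feature — is the data-density-weighted mean |centered mean PDP|; for a
single-split stump with probability jump Δp under a symmetric density this
equals Δp/2.  Monotonicity of a curve is judged with a −10⁻³ tie tolerance
per grid step, since tree-ensemble PDPs are step functions.
Misclassification curves smooth the per-observation error indicator along a
feature axis with a Gaussian kernel (Silverman bandwidth); |Spearman ρ|
between feature value and error above 0.2 flags a "clear trend", the
signature of a decision function that does not generalize along that
feature.

## Synthetic cohorts

The generator plants everything downstream stages estimate, at two levels.

**Signal level.**  Nights follow the wear protocol (4 h before bed to 4 h
after reported wake).  Bedtime is ~23:00 with participant and night jitter;
latency is 2 min + exponential (mean 12 min); duration is participant mean
7.2 h (between-SD 0.5 h) with within-SD 0.75 h — values a field study of
young adults would consider typical.  Planted IBIs are Gaussian per phase
(asleep HR ≈ participant resting HR ~N(62, 5) bpm, awake +12 bpm; IBI SD 35
ms awake / 55 ms asleep, clipped to 400–1600 ms).  BVP renders one pulse
template (systolic peak + dicrotic bump) per beat plus Gaussian noise at a
target SNR (default 10 dB).  The device IBI file is the planted beat list
with Poisson motion-artifact segments removed (10/h awake, 1.5/h asleep,
60–400 s).  EDA is a drifting tonic level with a deterministic 0.03 µS
per-second ripple (so background blocks can never flatline) and planted
artifact segments of all three kinds, placed so the analytically-known
block mask is exactly what the rules recover — including the rate-violation
block at the drop into a low-contact segment.  ACC is gravity plus sensor
noise, with 3 Hz movement bursts in ~35% of awake seconds and brief
low-amplitude arousals during sleep, quantized to the device's 1/64 g grid.
Temperature rises 1.6 °C after onset and falls after wake through
15-minute logistic transitions.

**Label model.**  latent = Σ coeff_f · z_f + participant intercept
(SD 0.5) + Gaussian noise, with z_f the within-participant z-score; the
latent maps to 1–5 through quantile cuts at (0.10, 0.30, 0.65, 0.90),
mimicking the skew toward "normal"/"good" responses in real sleep diaries.
Signal-level cohorts compute the latent from planted quantities (duration,
latency, phase HR/RMSSD); feature-level cohorts
(`simulate_observations`) draw 52-feature vectors directly from a
participant-random-effects model (between-SD 1, within-SD 1) — the scale at
which the modeling and interpretation stages are exercised, since rendering
hundreds of full-rate signal nights is not needed to test them.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: physiologically faithful PPG morphology and
motion-artifact structure, skin-conductance response dynamics beyond the
validity rules, circadian temperature beyond a single nightly profile,
inter-feature correlation, and label models other than additive-in-z.
Recovery results on synthetic cohorts demonstrate the pipeline's
correctness, not field accuracy.

## Problem sizes and determinism

Verification runs use: 10 000 random windows for the HRV oracle; 30 minutes
of 10 dB BVP (≈ 2 000 beats) for beat recovery; 100 nights for sleep-period
recovery; a 20 × 30-night cohort for effect recovery (LOSO repeated 3×;
permutation null over label shuffles with a 200-tree ensemble, whose null
behavior is insensitive to ensemble size); and 100 bootstrap replicates
with a 200-row PDP evaluation subsample for interpretation.  The importance
rank-correlation check plants a graded spectrum of eight nonzero
coefficients and correlates importance with |coefficient| over those
planted features — rank correlation over all 52 features would be dominated
by ties among the zero coefficients.  Every random quantity derives from
explicit integer seeds: per-participant streams are seeded by (seed,
CRC32(participant), night), so cohorts are reproducible and compose
participant-wise.

## Known limitations

* The Sadeh/Cole-Kripke coefficients were published for specific count
  recipes; this package's recipe is calibrated to their thresholds rather
  than reproducing the original devices' counts.
* The beat detector targets clean-ish wrist PPG; it is not a substitute for
  morphology-aware detectors on heavily corrupted field data.
* The GAM with all 52 features on cohort-scale data is fit by its ridge
  fallback; its curves are then shrunk toward linearity.
* Sleep-period estimation inherits actigraphy's known ~10–20 minute error
  scale; nights without a qualifying 10-minute sleep run are dropped.
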