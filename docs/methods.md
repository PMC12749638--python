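# Methods

This note documents the models, parameter choices and numerical decisions
behind `vocmotion`, in the order the pipeline runs.

## Synchronisation

Audio and accelerometer streams share no carrier (44.1 kHz acoustic
pressure vs 60 Hz acceleration), so the clock offset is estimated on
amplitude envelopes. Clap transients are detected on the short-time audio
envelope with an adaptive threshold (median + k·MAD over the first 60 s,
default k = 8, minimum peak spacing 0.15 s); fewer than the expected five
claps is a quality error, not a guess. The lag estimate proceeds in two
stages: (1) a normalised sliding template match of the audio clap-burst
envelope within the mean caregiver-hand magnitude envelope, both at 60 Hz
and smoothed with the same 100 ms window, searched over ±10 s with a
parabolic sub-sample peak fit; (2) a refinement that aligns each detected
audio clap with the nearest hand-magnitude peak and takes the median
offset. Stage 2 removes the residual bias that envelope-shape mismatch
(sharp acoustic transient vs mechanically ringing hand sensor) leaves in
the correlation peak; on synthesised sessions the combined estimator
recovers lags drawn U(−2, 2) s within one 60 Hz sample. One global lag per
session is applied — the wireless sensor bus is commonly synchronised, and
nothing in the data model supports per-sensor offsets. Clock-rate drift is
out of scope.

A lag is *positive* when the accelerometer clock runs behind the audio
clock; `apply_lag` subtracts it from accelerometer timestamps.

## Preprocessing

Dropped packets (time step > 1.5× the nominal interval, or non-finite
samples) are re-inserted on the nominal grid and cubic-spline interpolated
per axis; interpolated samples stay flagged, and any epoch overlapping a
flagged sample is excluded, so reconstructed data never reach the
statistics. Gaps at the record boundary are trimmed (splines cannot
extrapolate safely). Rate-dropped stretches are returned to 60 Hz — by
polyphase resampling when the whole record is uniform, by cubic
interpolation onto the target grid otherwise.

The magnitude Acc(t) = sqrt(x² + y² + z²) is taken per sample *before*
filtering, and the gravity/DC component is removed by a 2nd-order 1 Hz
Butterworth highpass. Filtering is zero-phase (forward–backward) by
default: the analysis windows are ±0.9 s around onset, and a causal filter
would shift event-locked features by its group delay; the squared
magnitude response this implies is what the response tests check. A
single-pass option is retained behind a flag. No quaternion gravity
decomposition is attempted — the highpass removes the quasi-static
component, which is all the envelope analysis needs.

Throw artifacts (the infant removing/throwing a sensor) are masked where
|Acc| exceeds a threshold, dilated by a 50 ms guard. The threshold is
calibration data in spirit; absent a session-specific value the default is
median + 10·MAD of the magnitude series. Masked runs longer than 0.6 s are
reported in QC but still masked.

## Epoching and the dependent measure

Epochs span [−3.5, +5] s around each vocalisation onset at 60 Hz
(511 samples; onset snapped to the nearest sample, index 210). Windows are
half-open — baseline [−2.5, −0.9), pre [−0.9, 0), during [0, 0.9) — giving
deterministic 96/54/54 sample counts; the onset sample belongs to
"during". The ±0.9 s boundary is fixed; `locate_inflection` reports where
the curvature of a mean audio envelope would put it, as a diagnostic only.

Baseline correction is the envelope-mean method: natural cubic splines
through local maxima and minima (minimum peak separation 2 samples,
endpoints anchored; a constant segment degenerates to itself), averaged
over the [+3.5, +5] s reference span, subtracted as a scalar. The
correction is shift-invariant and idempotent. The reference span sits
*after* the vocalisation — deliberately preserved as specified upstream,
and overridable in `WindowBounds`.

The analytic envelope uses a 12-tap equiripple FIR Hilbert transformer
(type IV, passband 0.08–0.42 of the sample rate) paired with a
matched-delay windowed-sinc on the in-phase branch; the shared 5.5-sample
group delay is compensated by an interpolating shift, so the envelope is
phase-preserving up to edge effects. Against the full FFT Hilbert oracle
the mid-epoch error is below 5% for tones in the 5–12 Hz movement band;
accuracy degrades below ~4 Hz, an intrinsic limit of 12 taps at 60 Hz.

Per event, limb and window, the median envelope value is computed per side
and the two sides averaged; one event × limb × window median is the
statistical unit fed to the models (per-infant aggregation exists for
plotting only). Epochs whose tail contains the next onset are flagged and
retained by default (configurable exclusion); events missing one side
contribute the available side, flagged.

## Statistical models

Four families, all grouped by infant:

1. **Global:** median ~ Time_Point × Time_Window × Limb +
   (1 + Limb | infant). Selected among an eight-model lattice — four fixed
   structures (main effects; + window:age; all two-way; full triple
   interaction) crossed with two random structures (intercept only;
   intercept + limb slope) — fitted by ML and compared on AIC/BIC/logLik
   with an LRT of the triple interaction.
2. **Window × age:** median ~ Time_Window × Time_Point +
   (1 + Limb | infant), with base/pre/during pairwise contrasts.
3. **Per-window age × limb:** median_w ~ Time_Point × Limb +
   (1 + Limb | infant) for each window, with leg−arm contrasts.
4. **Baseline-corrected:** diff_pre / diff_during ~ Time_Point × Limb +
   (1 | infant) — the baseline subtraction removes most infant-level
   variance, and the limb slope is no longer supported.

Estimation is ML wherever structures are compared (valid likelihood
comparison) and REML for all reported coefficients, ANOVA tables and
contrasts. Fits go through statsmodels MixedLM with an optimizer fallback
chain; the log-likelihood is recomputed in the lme4 convention (REML
criterion includes log|XᵀV⁻¹X| and (n−p)·log 2π), and the parameter count
is p + #variance parameters including σ², so AIC/BIC/LRT arithmetic
matches the lmer ecosystem.

The inference layer is implemented in-package and cross-checked against R
(lme4 1.1, lmerTest 3.1, emmeans 1.11) in the test suite:

- **Satterthwaite df.** For a contrast ℓ, df = 2C²/(gᵀAg) with
  C = ℓᵀΦℓ, Φ = (XᵀV⁻¹X)⁻¹, g the central-difference gradient of C in the
  variance parameters θ = (σ², vech G), and A the inverse observed REML
  information (numerical Hessian). All V⁻¹ quantities use the Woodbury
  identity on per-group sufficient statistics, so the Hessian and the
  perturbed Φ(θ ± h) cost almost nothing regardless of N. Multi-df terms
  diagonalise LΦLᵀ and combine one-df components via 2E/(E − q),
  E = Σ νᵢ/(νᵢ − 2), exactly as lmerTest does. If the information matrix
  is unavailable (boundary fits), a residual-df fallback is used and
  flagged in the output — never silently.
- **Type-II tests** follow the lmerTest construction: a term contained in
  no other term keeps its raw coefficient rows; any other term is
  orthogonalised against all terms not containing it by a Doolittle
  decomposition of XᵀX with the term's (and its relatives') columns
  ordered last. This is invariant to factor-level order up to optimizer
  tolerance.
- **Contrasts** are differences of reference-grid marginal means with
  equal weights over unnamed factors, SEs from Φ, Satterthwaite df, and
  Bonferroni correction over the printed family: window pairs (m = 3),
  leg−arm within age (m = 4), leg−arm overall (m = 1), and the
  age-progression block (m = 10).
- **Effect sizes.** Omnibus rows: f = sqrt(NumDF·F/DenDF) and
  η²ₚ = NumDF·F/(NumDF·F + DenDF), which satisfy f² = η²ₚ/(1 − η²ₚ).
  Contrast rows use the t-based convention f = |t|/√N_obs and are labelled
  as such — the literature convention for post-hoc f denominators is not
  standardised.
- **Random-effect tests** are matched-criterion LRTs (slope + correlation:
  df = 2; intercept vs none: df = 1, against the analytic REML
  log-likelihood of the fixed-effects model); the output notes that the
  boundary null makes the χ² reference conservative.
- **R²** follows the variance-decomposition convention: marginal =
  var(Xβ)/total, conditional adds the mean of diag(ZGZᵀ); total includes
  σ².

## The synthetic generator

`simulate_rows` draws event-level medians straight from the mixed model —
the distributional layer used for calibration studies. `simulate_cohort`
renders full sessions: audio (background noise floor σ = 0.01, Tukey-
windowed noise bursts of amplitude 0.3 per utterance, five 0.9-amplitude
clap transients from 5 s at 0.7 s spacing) and accelerometer channels
whose z-axis carries gravity plus an oscillatory carrier — band-limited
2–8 Hz Gaussian noise normalised to unit median envelope, or a pure 8 Hz
sine (the flat-gain point of the envelope chain) for noise-free
calibration — amplitude-modulated to the target envelope. With the sine
carrier and no noise, the full pipeline recovers injected window medians
to <0.3% relative error.

Defaults are the study conditions: ~313 s sessions, 6 vocalisations/min
(Poisson onsets thinned by a 0.5 s refractory — roughly one expiration
cycle; utterances are truncated at the next onset), lognormal durations
with mean ≈ 0.59 s (µ = −0.775, σ = 0.71), four visits at 4/6/9/12 months,
whole-visit attrition 0.129. The coupling structure: window increments of
0.21 (pre) and 0.31 (during) m/s² with a limb split that puts legs above
arms at 4–6 months and arms above legs at 9–12 months, both in the
baseline level and in the increments; residual sd 1.2 m/s² at the
event-median level; random-effect sds 0.55 (intercept) and 0.35 (limb
slope) with correlation −0.3, reproducing a variance decomposition in
which fixed effects explain ~2% and infant-level effects a further ~23% of
the total. The *absolute* baseline level (~0.5 m/s²) is an
order-of-magnitude choice — no physical-unit baselines were available to
anchor it — and is flagged as such.

Field realities injected per channel: two dropped-packet gaps
(0.1–0.5 s), one 5 s 60→40 Hz rate-drop stretch, two ±50 m/s² throw
artifacts of 0.2–0.6 s, and a session-wide audio-IMU lag (default 0.35 s).

What the generator does *not* emulate: acoustically realistic infant
vocalisations (bursts are broadband noise), caregiver speech, sensor
orientation dynamics (the oscillation rides on a fixed gravity axis),
clock drift, and correlated left/right asymmetries. Passing tests
therefore demonstrate that the pipeline recovers the assumed statistical
structure through the full signal chain — not that real infant data meet
those assumptions.

## Calibration studies and problem sizes

The simulation studies run on the row layer at sizes chosen to finish in a
few minutes on one CPU: sync recovery over 50 sessions of 25 s; window
ordering/crossover recovery over 50 cohorts of 60 infants × 40
events/visit; CI coverage over 200 cohorts of 60 infants × 8 events/visit
(sd_intercept 0.3, sd_slope 0.2); type-I control over 200 zero-coupling
cohorts of 20 infants × 8 events/visit. Full-signal replication at these
replicate counts would add nothing statistically — the signal layer is
validated separately by the noise-free calibration and end-to-end smoke
tests.

## Known limitations

- The 12-tap Hilbert envelope under-reads below ~4 Hz; slow flailing
  movements are attenuated relative to faster ones.
- Satterthwaite df relies on an interior optimum of the variance
  parameters; singular fits fall back to residual df (flagged).
- The Type-II/Satterthwaite layer is validated against R on
  intercept+slope structures with two crossed factors; more exotic random
  structures are out of scope.
- TextGrid support covers the long and short *text* dialects only; binary
  TextGrids are rejected with instructions to re-save.
- One vocalisation tier per session; overlapping annotated intervals are
  treated as a coding error.
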