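# vocmotion

Event-locked analysis of infant limb movement around vocalisation onsets.

During the first year of life, infant vocalisations co-occur with bursts of
limb movement — motor-vocal coupling that may scaffold later speech-gesture
coordination. `vocmotion` implements a complete pipeline for quantifying
this coupling from semi-naturalistic dyad recordings: session audio
(44.1 kHz WAV) with utterance-level Praat TextGrid annotations, plus
wrist/ankle 3-axis accelerometers (nominal 60 Hz) on the infant and clap-sync
hand sensors on the caregiver. It is written for developmental and
movement-science researchers who need the full chain — synchronisation, signal
conditioning, event-locked epoching, and mixed-effects inference — as tested,
scriptable Python.

## The analysis

1. **Clock alignment.** A five-clap burst at the session start appears as
   acoustic peaks and as acceleration transients on the caregiver's hands.
   The audio amplitude envelope and the mean hand acceleration magnitude
   envelope are cross-correlated at a common 60 Hz; the correlation peak
   (parabolic-interpolated, then refined per clap) gives one session-wide
   lag applied to all accelerometer timestamps.
2. **Preprocessing.** Dropped packets are cubic-spline interpolated,
   rate-dropped segments resampled back to 60 Hz, and each channel reduced
   to the magnitude Acc(t) = sqrt(x² + y² + z²), then highpassed
   (Butterworth, 2nd order, 1 Hz, zero-phase) to remove gravity. Brief
   high-amplitude "sensor throw" segments are masked.
3. **Epoching.** Each vocalisation onset defines an epoch over [−3.5, +5] s.
   Epochs are centred by an envelope baseline correction (mean of the
   upper/lower peak-spline envelopes over the [+3.5, +5] s reference span)
   and reduced to the analytic envelope via a 12-tap FIR Hilbert pair.
   Medians over three windows — baseline [−2.5, −0.9) s, pre [−0.9, 0) s,
   during [0, 0.9) s — are computed per side and averaged per limb.
4. **Statistics.** Event-level window medians feed linear mixed models with
   per-infant random intercepts and limb slopes:

   median ~ Time_Point × Time_Window × Limb + (1 + Limb | infant) + ε

   plus a window × age model, per-window age × limb models, and
   baseline-corrected difference models with intercept-only random effects.
   Reporting matches the lme4/lmerTest/emmeans conventions: ML model
   comparison over an eight-model lattice (AIC/BIC/logLik, LRTs), REML
   Type-II ANOVA with Satterthwaite denominator df, estimated-marginal-mean
   contrasts with Bonferroni correction, Cohen's f effect sizes
   (f = sqrt(NumDF·F/DenDF)), and Nakagawa marginal/conditional R².

A synthetic dyad-session generator (`vocmotion.synthetic`) renders complete
cohorts — audio with vocalisation bursts and claps, accelerometer channels
whose oscillation envelope carries a known mixed-model structure, dropped
packets, 60→40 Hz rate drops, throw artifacts, clock offsets and missing
visits — so every stage is testable with no data download.

## Worked example

```python
from vocmotion.synthetic import SimConfig, simulate_cohort
from vocmotion.pipeline import PipelineConfig, run_pipeline
import glob, json

cfg = SimConfig(n_infants=3, timepoints=(6, 9), session_duration=50.0,
                voc_rate=16.0, missing_visit_prob=0.0)
simulate_cohort(cfg, seed=31, out_dir="demo_cohort")

pc = PipelineConfig(manifests=sorted(glob.glob("demo_cohort/*/session.yaml")),
                    out_dir="demo_out", lattice=False)
out = run_pipeline(pc)
report = json.load(open("demo_out/report.json"))
ct = report["window_by_age"]["contrasts"]["window_pairs"]
for row in ct:
    print(f"{row['contrast']:>14}: {row['estimate']:+.3f} m/s^2 "
          f"(p_bonf = {row['p_bonferroni']:.2e})")
```

prints

```
    base - pre: -0.181 m/s^2 (p_bonf = 5.46e-02)
 base - during: -0.250 m/s^2 (p_bonf = 3.87e-03)
  pre - during: -0.069 m/s^2 (p_bonf = 1.00e+00)
```

i.e. limb acceleration in this simulated cohort rises from the silent
baseline into the second before vocalisation onset and rises further during
the vocalisation itself — the injected coupling (+0.21 and +0.31 m/s²
population increments) is recovered with the correct ordering, though at
three infants only the largest contrast is significant after Bonferroni
correction; the calibration studies run this recovery at realistic cohort
sizes. Each session's QC (estimated
lag, clap correlation, masked seconds, epoch exclusions) lands in
`demo_out/qc.json`, and the per-age grand-average envelope panels in
`demo_out/figures/`.

The same flow is available from the shell:

```bash
vocmotion simulate --out demo_cohort --seed 31
vocmotion run-all demo_cohort --out demo_out
```

## Layout

| module | contents |
| --- | --- |
| `io_formats` | WAV, Praat TextGrid (long/short), accelerometer CSV, YAML manifests, TSV summaries |
| `synthetic` | dyad-session and cohort generator with ground truth |
| `sync_qc` | clap detection, lag estimation, artifact masking |
| `preprocess` | gap filling, resampling, magnitude, highpass |
| `epoching` | epochs, envelope baseline correction, analytic envelope, window medians |
| `lmm`, `stats` | mixed models, Satterthwaite/Type-II/emmeans layer, model suite |
| `calibration` | simulation studies (sync, recovery, coverage, type-I) |
| `pipeline`, `cli` | orchestration, plots, `vocmotion` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
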