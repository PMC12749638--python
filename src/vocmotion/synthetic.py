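"""Synthetic dyad sessions and cohorts with known ground truth.

The generator emulates the statistical and signal structure the analysis
assumes, at two layers:

* :func:`simulate_rows` draws event-level window medians directly from the
  linear mixed model the pipeline fits — per-infant random intercepts and
  limb slopes, additive window/limb/age effects, i.i.d. residuals.  This is
  the distributional core used for calibration studies (type-I error,
  coverage, recovery) where hundreds of replicate fits are needed.
* :func:`simulate_cohort` renders full sessions — 44.1 kHz audio with
  vocalisation bursts and a five-clap synchronisation event, TextGrid
  annotations, and 60 Hz accelerometer channels whose oscillation envelope
  carries the same mixed-model structure, plus the field realities the
  pipeline must survive: a fixed audio-IMU clock offset, dropped packets,
  60->40 Hz rate-drop segments, brief high-amplitude throw artifacts and
  missing visits.

Default parameters are the study conditions: ~5-minute sessions, ~6
vocalisations/minute with lognormal durations around 0.59 s, window
increments of 0.21 (pre) and 0.31 (during) m/s^2 with a limb-by-age
crossover, residual sd 1.2, random-effect sds 0.55 (intercept) and 0.35
(limb slope).  The absolute baseline level (~0.5 m/s^2) is an
order-of-magnitude choice; see docs/methods.md.
"""
from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .types import (AccChannel, AudioTrack, Placement, SessionManifest,
                    VocEvent, LIMBS, SIDES, TIME_POINTS, WINDOW_NAMES)
from . import io_formats


def _default_baseline() -> dict:
    # arm/leg baselines per age; legs drop once sitting frees the arms
    return {(4, "arm"): 0.50, (6, "arm"): 0.50, (9, "arm"): 0.63,
            (12, "arm"): 0.60,
            (4, "leg"): 0.50, (6, "leg"): 0.64, (9, "leg"): 0.24,
            (12, "leg"): 0.35}


def _default_deltas() -> dict:
    # window means 0.21/0.31 m/s^2 with a limb-by-age split
    split = {"pre": {4: 0.06, 6: 0.13, 9: -0.04, 12: -0.03},
             "during": {4: 0.12, 6: 0.23, 9: -0.04, 12: -0.09}}
    mean = {"pre": 0.21, "during": 0.31}
    out = {}
    for w in ("pre", "during"):
        for tp in TIME_POINTS:
            for limb, sgn in (("arm", -0.5), ("leg", +0.5)):
                out[(tp, limb, w)] = mean[w] + sgn * split[w][tp]
    return out


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_infants: int = 104
    timepoints: Tuple[int, ...] = TIME_POINTS
    session_duration: float = 313.0        # s
    voc_rate: float = 6.0                  # events / min
    refractory: float = 0.5                # s between onsets
    voc_start: float = 10.0                # earliest onset (after the claps)
    dur_logmean: float = -0.775            # lognormal -> mean ~0.593 s
    dur_logsd: float = 0.710
    events_per_visit: int = 40             # row-layer design size

    audio_rate: float = 44100.0
    noise_floor: float = 0.01
    voc_amp: float = 0.3
    clap_time: float = 5.0
    n_claps: int = 5
    clap_spacing: float = 0.7
    clap_amp: float = 0.9

    acc_rate: float = 60.0
    carrier: str = "noise"                 # "noise" | "sine"
    carrier_band: Tuple[float, float] = (2.0, 8.0)
    carrier_freq: float = 8.0              # Hz, sine carrier (flat-gain
                                           # point of the envelope chain)
    axis_noise: float = 0.02               # m/s^2 on off-axis channels
    env_noise_sd: float = 0.25             # per event x limb x window jitter
    min_envelope: float = 0.05             # m/s^2 floor for amplitudes

    baseline_level: dict = field(default_factory=_default_baseline)
    coupling_delta: dict = field(default_factory=_default_deltas)
    sd_intercept: float = 0.55
    sd_slope_limb: float = 0.35
    corr_int_slope: float = -0.30
    sd_resid: float = 1.2

    lag_audio_imu: float = 0.35            # s, acc clock behind audio
    n_gaps: int = 2
    gap_len: Tuple[float, float] = (0.1, 0.5)
    n_rate_drops: int = 1
    rate_drop_len: float = 5.0
    n_artifacts: int = 2
    artifact_len: Tuple[float, float] = (0.2, 0.6)
    artifact_amp: float = 50.0
    missing_visit_prob: float = 0.129      # whole-visit attrition

    seed: int = 0

    def __post_init__(self):
        for nm in ("sd_intercept", "sd_slope_limb", "sd_resid"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if abs(self.corr_int_slope) > 1:
            raise ValueError("|corr_int_slope| must be <= 1")
        if self.voc_rate <= 0:
            raise ValueError("voc_rate must be positive")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")

    def re_cov(self) -> np.ndarray:
        c = self.corr_int_slope * self.sd_intercept * self.sd_slope_limb
        return np.array([[self.sd_intercept ** 2, c],
                         [c, self.sd_slope_limb ** 2]])

    def delta(self, tp: int, limb: str, window: str) -> float:
        if window == "base":
            return 0.0
        return self.coupling_delta.get((tp, limb, window), 0.0)

    def cell_mean(self, tp: int, limb: str, window: str) -> float:
        return self.baseline_level[(tp, limb)] + self.delta(tp, limb, window)


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort, reproducible from
    (config, seed)."""

    seed: int
    lag: float
    random_effects: pd.DataFrame          # infant_id, u_intercept, u_slope
    sessions: List[dict]                  # per-session metadata
    artifacts: Dict[str, list] = field(default_factory=dict)
    gaps: Dict[str, list] = field(default_factory=dict)

    def to_json(self, path):
        doc = {
            "seed": self.seed, "lag": self.lag,
            "random_effects": self.random_effects.to_dict(orient="records"),
            "sessions": self.sessions,
            "artifacts": self.artifacts, "gaps": self.gaps,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)


# --------------------------------------------------------------------------
# Event trains
# --------------------------------------------------------------------------

def simulate_voc_train(config: SimConfig, seed=None) -> List[VocEvent]:
    """Homogeneous Poisson vocalisation onsets thinned by the refractory
    constraint, with lognormal durations; all events fit in the session."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.voc_start, config.session_duration
    if hi <= lo:
        return []
    n = rng.poisson(config.voc_rate / 60.0 * (hi - lo))
    onsets = np.sort(rng.uniform(lo, hi, size=n))
    kept = []
    last = -np.inf
    for t in onsets:
        if t - last >= config.refractory:
            kept.append(t)
            last = t
    if n > 0 and not kept:
        warnings.warn("refractory constraint removed every event; "
                      "returning best-effort train", stacklevel=2)
    durations = rng.lognormal(config.dur_logmean, config.dur_logsd,
                              size=len(kept))
    events = []
    for i, (t, d) in enumerate(zip(kept, durations)):
        if t + 1e-3 >= hi:
            continue
        # an utterance ends before the next begins (one expiration cycle)
        nxt = kept[i + 1] - 1e-3 if i + 1 < len(kept) else hi
        off = min(t + d, nxt, hi)
        if off <= t:  # degenerate spacing (possible only without refractory)
            off = min(t + 1e-3, hi)
        events.append(VocEvent(onset=float(t), offset=float(off),
                               label="protophone"))
    return events


# --------------------------------------------------------------------------
# Audio synthesis
# --------------------------------------------------------------------------

def clap_times(config: SimConfig) -> np.ndarray:
    return config.clap_time + np.arange(config.n_claps) * config.clap_spacing


def synth_audio(events: Sequence[VocEvent], claps: Sequence[float],
                config: SimConfig, seed=None) -> AudioTrack:
    """Noise floor + windowed noise bursts per utterance + sharp clap
    transients, at 44.1 kHz on the session clock."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.audio_rate
    n = int(round(config.session_duration * fs))
    x = rng.normal(0.0, config.noise_floor, size=n)
    for ev in events:
        i0 = int(round(ev.onset * fs))
        i1 = min(int(round(ev.offset * fs)), n)
        if i1 - i0 < 8:
            continue
        burst = rng.normal(0.0, 1.0, size=i1 - i0)
        win = signal.windows.tukey(i1 - i0, alpha=0.2)
        x[i0:i1] += config.voc_amp * win * burst
    dur_c = 0.008
    n_c = int(round(dur_c * fs))
    t_c = np.arange(n_c) / fs
    shape = np.exp(-t_c / 0.002)
    for tc in claps:
        i0 = int(round(tc * fs))
        if 0 <= i0 < n - n_c:
            x[i0:i0 + n_c] += config.clap_amp * shape * np.sign(
                rng.normal(size=n_c) + 1e-12)
    np.clip(x, -1.0, 1.0, out=x)
    return AudioTrack(samples=x, rate=fs, t0=0.0)


# --------------------------------------------------------------------------
# Accelerometer synthesis
# --------------------------------------------------------------------------

GRAVITY = 9.81


def _carrier(n: int, config: SimConfig, rng) -> np.ndarray:
    """Unit-envelope oscillatory carrier at the accelerometer rate."""
    if config.carrier == "sine":
        t = np.arange(n) / config.acc_rate
        return np.sin(2 * np.pi * config.carrier_freq * t)
    white = rng.normal(size=n)
    sos = signal.butter(4, config.carrier_band, btype="bandpass",
                        fs=config.acc_rate, output="sos")
    band = signal.sosfiltfilt(sos, white)
    env = np.abs(signal.hilbert(band))
    scale = np.median(env)
    return band / scale if scale > 0 else band


def _target_envelope(t: np.ndarray, events, level: float, tp: int,
                     limb: str, config: SimConfig, rng) -> np.ndarray:
    env = np.full(t.size, max(level, config.min_envelope))
    for ev in events:
        for w, (a, b) in (("pre", (ev.onset - 0.9, ev.onset)),
                          ("during", (ev.onset, ev.onset + 0.9))):
            jitter = rng.normal(0.0, config.env_noise_sd) \
                if config.env_noise_sd > 0 else 0.0
            sel = (t >= a) & (t < b)
            env[sel] = np.maximum(
                level + config.delta(tp, limb, w) + jitter,
                config.min_envelope)
    return env


def _degrade(t, x, y, z, config: SimConfig, rng):
    """Inject gaps, a 40 Hz rate-drop segment, and throw artifacts.

    Returns (t, x, y, z, artifact_spans, gap_spans) with samples *removed*
    for gaps (dropped packets) and *decimated* over rate-drop spans.
    """
    dur = t[-1] - t[0]
    art_spans, gap_spans = [], []
    for _ in range(config.n_artifacts):
        ln = rng.uniform(*config.artifact_len)
        a = rng.uniform(config.voc_start, t[0] + dur - ln)
        sel = (t >= a) & (t < a + ln)
        z[sel] += config.artifact_amp * rng.choice([-1.0, 1.0])
        art_spans.append((float(a), float(a + ln)))
    for _ in range(config.n_rate_drops):
        # the tracker silently halves-to-40-Hz for a stretch: replace the
        # span with a uniform 25 ms grid
        ln = config.rate_drop_len
        a = rng.uniform(config.voc_start, t[0] + dur - ln)
        td = np.arange(a, a + ln, 1.0 / 40.0)
        pre, post = t < a, t >= a + ln
        x, y, z = (np.concatenate((v[pre], np.interp(td, t, v), v[post]))
                   for v in (x, y, z))
        t = np.concatenate((t[pre], td, t[post]))
    keep = np.ones(t.size, dtype=bool)
    for _ in range(config.n_gaps):
        ln = rng.uniform(*config.gap_len)
        a = rng.uniform(config.voc_start, t[0] + dur - ln)
        keep &= ~((t > a) & (t < a + ln))
        gap_spans.append((float(a), float(a + ln)))
    return (t[keep], x[keep], y[keep], z[keep], art_spans, gap_spans)


def synth_acc(events: Sequence[VocEvent], infant_effects: Tuple[float, float],
              tp: int, config: SimConfig, seed=None, degrade: bool = True):
    """Six accelerometer channels for one session.

    Four infant channels (arm/leg x left/right) carry a band-limited
    oscillation whose amplitude envelope is baseline + random effects +
    coupling increments over the pre/during windows of each event, riding
    on gravity along z.  Two caregiver hand channels carry the clap
    transients.  All timestamps sit on the accelerometer clock, i.e.
    session time + ``lag_audio_imu``.

    Returns (channels, truth) with per-channel artifact and gap spans.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    u0, u1 = infant_effects
    fs = config.acc_rate
    n = int(round(config.session_duration * fs))
    tau = np.arange(n) / fs  # session (audio) clock
    channels = []
    truth = {"artifacts": {}, "gaps": {}}
    for limb in LIMBS:
        level = (config.baseline_level[(tp, limb)] + u0
                 + (u1 if limb == "leg" else 0.0))
        for side in SIDES:
            pl = Placement("infant", limb, side)
            amp = _target_envelope(tau, events, level, tp, limb, config, rng)
            carrier = _carrier(n, config, rng)
            zsig = GRAVITY + amp * carrier
            if config.axis_noise > 0:
                x = rng.normal(0, config.axis_noise, n)
                y = rng.normal(0, config.axis_noise, n)
            else:
                x = np.zeros(n)
                y = np.zeros(n)
            t = tau + config.lag_audio_imu
            if degrade:
                t, x, y, zsig, arts, gaps = _degrade(
                    t.copy(), x, y, zsig.copy(), config, rng)
            else:
                arts, gaps = [], []
            truth["artifacts"][pl.key] = arts
            truth["gaps"][pl.key] = gaps
            channels.append(AccChannel(t=t, x=x, y=y, z=zsig, rate=fs,
                                       placement=pl))
    pulse_shape = np.exp(-np.arange(int(0.15 * fs)) / (0.03 * fs))
    for side in SIDES:
        pl = Placement("caregiver", "hand", side)
        zsig = np.full(n, GRAVITY) + rng.normal(0, 0.05, n)
        for tc in clap_times(config):
            i0 = int(round(tc * fs))
            if 0 <= i0 < n - pulse_shape.size:
                zsig[i0:i0 + pulse_shape.size] += 30.0 * pulse_shape
        channels.append(AccChannel(
            t=tau + config.lag_audio_imu,
            x=rng.normal(0, 0.05, n), y=rng.normal(0, 0.05, n), z=zsig,
            rate=fs, placement=pl))
    return channels, truth


# --------------------------------------------------------------------------
# Sessions and cohorts
# --------------------------------------------------------------------------

@dataclass
class SessionData:
    """One simulated session, in memory."""

    infant_id: str
    time_point: int
    audio: AudioTrack
    events: List[VocEvent]
    channels: List[AccChannel]

    def to_disk(self, directory) -> SessionManifest:
        os.makedirs(directory, exist_ok=True)
        audio_path = os.path.join(directory, "audio.wav")
        io_formats.write_wav(audio_path, self.audio)
        tg_path = os.path.join(directory, "vocalisations.TextGrid")
        io_formats.write_textgrid(tg_path, self.events,
                                  xmax=self.audio.duration)
        acc_paths = {}
        for ch in self.channels:
            p = os.path.join(directory, f"acc_{ch.placement.key}.csv")
            io_formats.write_acc_table(p, ch)
            acc_paths[ch.placement] = p
        manifest = SessionManifest(
            infant_id=self.infant_id, time_point=self.time_point,
            audio_path=audio_path, annotation_path=tg_path,
            acc_paths=acc_paths)
        io_formats.write_manifest(os.path.join(directory, "session.yaml"),
                                  manifest)
        return manifest


def simulate_session(infant_id: str, tp: int, effects, config: SimConfig,
                     seed, degrade: bool = True):
    """(SessionData, truth dict) for one infant visit."""
    rng = np.random.default_rng(seed)
    s_train, s_audio, s_acc = rng.integers(0, 2 ** 31, size=3)
    events = simulate_voc_train(config, s_train)
    audio = synth_audio(events, clap_times(config), config, s_audio)
    channels, ch_truth = synth_acc(events, effects, tp, config, s_acc,
                                   degrade=degrade)
    return SessionData(infant_id, tp, audio, events, channels), ch_truth


def simulate_cohort(config: SimConfig, seed=None, out_dir=None,
                    degrade: bool = True):
    """Full longitudinal cohort.

    Returns (sessions, truth): in-memory SessionData per infant x visit
    (whole visits dropped at the attrition probability), with per-infant
    random effects shared across visits.  With ``out_dir`` every session
    is also written to disk (WAV + TextGrid + acc CSVs + manifest) along
    with ``truth.json``.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cov = config.re_cov()
    effects = rng.multivariate_normal([0.0, 0.0], cov, size=config.n_infants)
    re_df = pd.DataFrame({
        "infant_id": [f"inf{i:03d}" for i in range(config.n_infants)],
        "u_intercept": effects[:, 0], "u_slope": effects[:, 1]})
    sessions, meta = [], []
    artifacts, gaps = {}, {}
    for i in range(config.n_infants):
        for tp in config.timepoints:
            missed = rng.random() < config.missing_visit_prob
            if missed:
                continue
            s_seed = int(rng.integers(0, 2 ** 31))
            sess, ch_truth = simulate_session(
                re_df.infant_id[i], tp, effects[i], config, s_seed,
                degrade=degrade)
            key = f"{sess.infant_id}_t{tp}"
            artifacts[key] = ch_truth["artifacts"]
            gaps[key] = ch_truth["gaps"]
            meta.append({"infant_id": sess.infant_id, "time_point": tp,
                         "n_events": len(sess.events), "seed": s_seed})
            sessions.append(sess)
    truth = SimTruth(seed=seed, lag=config.lag_audio_imu,
                     random_effects=re_df, sessions=meta,
                     artifacts=artifacts, gaps=gaps)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for sess in sessions:
            sess.to_disk(os.path.join(out_dir,
                                      f"{sess.infant_id}_t{sess.time_point}"))
        truth.to_json(os.path.join(out_dir, "truth.json"))
    return sessions, truth


# --------------------------------------------------------------------------
# Row-level simulator (the distributional core)
# --------------------------------------------------------------------------

def simulate_rows(config: SimConfig, seed=None, attrition: bool = False
                  ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Event-level window medians drawn straight from the mixed model.

    One row per infant x time point x event x limb x window, with
    ``events_per_visit`` events per visit.  Returns (rows, random_effects).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cov = config.re_cov()
    effects = rng.multivariate_normal([0.0, 0.0], cov, size=config.n_infants)
    recs = []
    for i in range(config.n_infants):
        u0, u1 = effects[i]
        iid = f"inf{i:03d}"
        for tp in config.timepoints:
            if attrition and rng.random() < config.missing_visit_prob:
                continue
            for e in range(config.events_per_visit):
                for limb in LIMBS:
                    mu_re = u0 + (u1 if limb == "leg" else 0.0)
                    for w in WINDOW_NAMES:
                        mu = config.cell_mean(tp, limb, w) + mu_re
                        recs.append((iid, tp, limb, w, e,
                                     mu + rng.normal(0, config.sd_resid)))
    rows = pd.DataFrame(recs, columns=["infant_id", "time_point", "limb",
                                       "window", "event", "median"])
    re_df = pd.DataFrame({
        "infant_id": [f"inf{i:03d}" for i in range(config.n_infants)],
        "u_intercept": effects[:, 0], "u_slope": effects[:, 1]})
    return rows, re_df


def cell_mean_table(config: SimConfig) -> pd.DataFrame:
    """True population cell means per time point x limb x window."""
    recs = [(tp, limb, w, config.cell_mean(tp, limb, w))
            for tp in config.timepoints for limb in LIMBS
            for w in WINDOW_NAMES]
    return pd.DataFrame(recs, columns=["time_point", "limb", "window",
                                       "mean"])
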