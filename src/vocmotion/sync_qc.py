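"""Audio-IMU clock alignment via the clap burst, plus throw-artifact masking.

Each session starts with a five-clap synchronisation event performed by the
caregiver.  The claps are sharp broadband transients, visible both as
acoustic peaks and as acceleration spikes on the caregiver's hands; the
session-wide clock offset is the argmax of the normalised cross-correlation
between the audio amplitude envelope and the mean hand acceleration
magnitude envelope, both at a common 60 Hz rate.

Sign convention: ``lag`` is positive when the accelerometer clock runs
*behind* the audio clock — a clap at audio time tau carries accelerometer
timestamp tau + lag.  ``apply_lag`` subtracts the lag from accelerometer
timestamps, putting them on the audio (session) clock.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import signal
from scipy.ndimage import binary_dilation

from .preprocess import magnitude
from .types import AccChannel, AudioTrack, MagnitudeSeries


class SyncQualityError(RuntimeError):
    """Synchronisation evidence too weak to trust."""


@dataclass(frozen=True)
class ClapEvent:
    time: float         # s, audio clock
    prominence: float   # envelope height above the adaptive threshold


@dataclass(frozen=True)
class LagEstimate:
    lag: float          # s, positive = accelerometer clock behind audio
    peak_corr: float    # normalised cross-correlation in [-1, 1]
    quality: str        # "ok" | "low"


@dataclass(frozen=True)
class SyncConfig:
    expected_claps: int = 5
    search_start: float = 0.0
    search_window: float = 60.0   # claps live in the first minute
    threshold_k: float = 8.0      # k in median + k*MAD
    min_spacing: float = 0.15     # s between clap peaks
    envelope_smooth: float = 0.002  # s, audio envelope smoothing
    max_lag: float = 10.0         # s, cross-correlation search half-window
    common_rate: float = 60.0     # Hz for the envelope cross-correlation
    min_quality: float = 0.5      # minimum acceptable peak correlation


def _smooth_envelope(x: np.ndarray, rate: float, width_s: float) -> np.ndarray:
    """Rectified signal smoothed by a moving average of ``width_s``."""
    n = max(1, int(round(width_s * rate)))
    kernel = np.ones(n) / n
    return np.convolve(np.abs(x), kernel, mode="same")


def detect_claps(audio: AudioTrack, config: SyncConfig = SyncConfig()
                 ) -> List[ClapEvent]:
    """Find clap transients in the early portion of the audio.

    Peaks of the short-time amplitude envelope exceeding an adaptive
    threshold (median + k*MAD over the search span) and separated by at
    least ``min_spacing`` are returned, sorted by time.
    """
    rate = audio.rate
    i0 = int(round((config.search_start - audio.t0) * rate))
    i1 = int(round((config.search_start + config.search_window - audio.t0)
                   * rate))
    seg = audio.samples[max(i0, 0):min(i1, audio.samples.size)]
    if seg.size == 0:
        raise SyncQualityError("audio has no samples in the clap search span")
    env = _smooth_envelope(seg, rate, config.envelope_smooth)
    med = np.median(env)
    mad = np.median(np.abs(env - med))
    thresh = med + config.threshold_k * max(mad, 1e-12)
    peaks, props = signal.find_peaks(
        env, height=thresh, distance=max(1, int(config.min_spacing * rate)))
    claps = [ClapEvent(time=audio.t0 + (max(i0, 0) + p) / rate,
                       prominence=float(h - thresh))
             for p, h in zip(peaks, props["peak_heights"])]
    if len(claps) < config.expected_claps:
        raise SyncQualityError(
            f"expected {config.expected_claps} claps, found {len(claps)}: "
            f"{[round(c.time, 3) for c in claps]}")
    return claps


def _envelope_at_rate(x: np.ndarray, rate: float, t0: float,
                      out_rate: float, t_lo: float, t_hi: float):
    """Frame-RMS envelope of x resampled onto an out_rate grid over
    [t_lo, t_hi]."""
    n_out = int(np.floor((t_hi - t_lo) * out_rate)) + 1
    t_grid = t_lo + np.arange(n_out) / out_rate
    win = max(1, int(round(rate / out_rate)))
    idx = np.round((t_grid - t0) * rate).astype(int)
    out = np.zeros(n_out)
    for k, i in enumerate(idx):
        a, b = max(i - win // 2, 0), min(i + win // 2 + 1, x.size)
        if a < b:
            out[k] = np.sqrt(np.mean(x[a:b] ** 2))
    return t_grid, out


def estimate_lag(audio: AudioTrack,
                 caregiver_hands: Sequence[AccChannel],
                 config: SyncConfig = SyncConfig()) -> LagEstimate:
    """Session clock offset from the clap burst.

    The audio amplitude envelope and the mean caregiver-hand acceleration
    magnitude envelope are put on a common 60 Hz grid around the detected
    claps and cross-correlated over +/- ``max_lag``; a parabolic fit around
    the integer-lag peak gives sub-sample resolution.
    """
    if not caregiver_hands:
        raise ValueError("need at least one caregiver hand channel")
    claps = detect_claps(audio, config)
    t_claps = np.array([c.time for c in claps[:config.expected_claps]])
    fs = config.common_rate
    pad = 1.5
    t_a0 = max(t_claps[0] - pad, float(audio.t0))
    t_a1 = t_claps[-1] + pad
    _, env_audio = _envelope_at_rate(audio.samples, audio.rate, audio.t0,
                                     fs, t_a0, t_a1)
    # mean hand magnitude on a wider grid (its own clock), then both
    # envelopes smoothed identically so the pulse shapes line up
    t_b0 = t_a0 - config.max_lag
    n_b = int(np.floor((t_a1 + config.max_lag - t_b0) * fs)) + 1
    t_b = t_b0 + np.arange(n_b) / fs
    hand = np.zeros(n_b)
    for ch in caregiver_hands:
        mag = magnitude(ch)
        hand += np.interp(t_b, mag.t, mag.value,
                          left=mag.value[0], right=mag.value[-1])
    hand /= len(caregiver_hands)
    smooth = max(1, int(round(0.1 * fs)))
    kern = np.ones(smooth) / smooth
    a = np.convolve(env_audio - np.median(env_audio), kern, mode="same")
    b_raw = np.abs(hand - np.median(hand))
    b = np.convolve(b_raw, kern, mode="same")
    # normalised sliding template match of the audio clap burst within the
    # hand stream
    a0 = a - a.mean()
    num = signal.correlate(b, a0, mode="valid")
    b2 = np.convolve(b ** 2, np.ones(a0.size), mode="valid")
    b1 = np.convolve(b, np.ones(a0.size), mode="valid")
    var_b = b2 - b1 ** 2 / a0.size
    denom = np.sqrt(np.sum(a0 ** 2) * np.clip(var_b, 1e-18, None))
    cc = (num - b1 * a0.mean() * 0.0) / denom  # a0 is zero-mean
    k = int(np.argmax(cc))
    lag = (t_b[k] - t_a0)
    if 0 < k < cc.size - 1:  # parabolic sub-sample peak
        y0, y1, y2 = cc[k - 1], cc[k], cc[k + 1]
        d2 = y0 - 2 * y1 + y2
        if abs(d2) > 1e-15:
            lag += 0.5 * (y0 - y2) / d2 / fs
    peak = float(cc[k])
    quality = "ok" if peak >= config.min_quality else "low"
    if quality == "low":
        raise SyncQualityError(
            f"clap cross-correlation peak {peak:.3f} below "
            f"{config.min_quality}; refusing low-confidence lag")
    # refine: align each audio clap with the nearest hand-magnitude peak
    offsets = []
    for tc in t_claps:
        sel = np.abs(t_b - (tc + lag)) <= 0.3
        if sel.any():
            seg = np.flatnonzero(sel)
            j = seg[int(np.argmax(b_raw[seg]))]
            offsets.append(t_b[j] - tc)
    if offsets:
        lag = float(np.median(offsets))
    if abs(lag) > config.max_lag:
        raise SyncQualityError(f"estimated lag {lag:.3f}s exceeds the "
                               f"+/-{config.max_lag}s search window")
    return LagEstimate(lag=float(lag), peak_corr=peak, quality=quality)


def apply_lag(channels: Sequence[AccChannel], lag: float
              ) -> List[AccChannel]:
    """Shift accelerometer timestamps onto the audio clock.

    Composes additively: apply_lag(apply_lag(c, a), b) == apply_lag(c, a+b).
    """
    if not np.isfinite(lag):
        raise ValueError("lag must be finite")
    out = []
    for ch in channels:
        shifted = ch.copy()
        shifted.t = shifted.t - lag
        out.append(shifted)
    return out


def detect_artifacts(series: MagnitudeSeries, threshold: float = None,
                     max_len: float = 0.6, guard: float = 0.05):
    """Mask brief high-amplitude segments (sensor throws).

    The threshold is required configuration in spirit — calibrated from
    throw events — with a data-driven default of median + 10*MAD of the
    magnitude series.  The exceedance mask is dilated by ``guard`` seconds
    on each side; contiguous runs longer than ``max_len`` are flagged in
    the returned QC info but still masked.

    Returns (mask, qc) where qc = {"threshold", "n_runs", "masked_seconds",
    "long_runs"}.
    """
    v = series.value
    if threshold is None:
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        threshold = med + 10.0 * max(mad, 1e-12)
    if threshold <= 0:
        raise ValueError("artifact threshold must be positive")
    hot = np.abs(v) > threshold
    g = int(round(guard * series.rate))
    mask = binary_dilation(hot, iterations=g) if (g > 0 and hot.any()) else hot
    # run-length QC
    long_runs = []
    n_runs = 0
    if mask.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8),
                                                       [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            n_runs += 1
            if (b - a) / series.rate > max_len:
                long_runs.append((float(series.t[a]),
                                  float(series.t[min(b, series.t.size) - 1])))
    qc = {"threshold": float(threshold), "n_runs": n_runs,
          "masked_seconds": float(mask.sum() / series.rate),
          "long_runs": long_runs}
    return mask, qc
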