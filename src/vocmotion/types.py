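"""Core domain containers shared across the pipeline.

All clocks are in seconds (double precision) on the *session clock*, whose
origin is the start of the audio recording.  Accelerations are in m/s^2.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

TIME_POINTS = (4, 6, 9, 12)
LIMBS = ("arm", "leg")
SIDES = ("left", "right")
WINDOW_NAMES = ("base", "pre", "during")

#: epoch grid: [-3.5, +5] s around vocalisation onset, sampled at 60 Hz
EPOCH_RATE = 60.0
EPOCH_START = -3.5
EPOCH_END = 5.0
EPOCH_LEN = int(round((EPOCH_END - EPOCH_START) * EPOCH_RATE)) + 1  # 511
ONSET_INDEX = int(round(-EPOCH_START * EPOCH_RATE))  # 210


def epoch_time_grid() -> np.ndarray:
    """Sample times of the epoch grid, with t=0 at the vocalisation onset."""
    return (np.arange(EPOCH_LEN) - ONSET_INDEX) / EPOCH_RATE


@dataclass(frozen=True)
class Placement:
    """Where a sensor sits: which wearer, which limb, which side."""

    wearer: str  # "infant" | "caregiver"
    limb: str    # "arm" | "leg" | "hand" | "head" | "torso"
    side: str    # "left" | "right" | "na"

    def __post_init__(self):
        if self.wearer not in ("infant", "caregiver"):
            raise ValueError(f"unknown wearer {self.wearer!r}")

    @property
    def key(self) -> str:
        return f"{self.wearer}_{self.limb}_{self.side}"


@dataclass
class AudioTrack:
    """Mono audio samples on the session clock."""

    samples: np.ndarray  # float in [-1, 1]
    rate: float          # Hz
    t0: float = 0.0      # seconds offset on the session clock

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("audio rate must be positive")
        if self.samples.size == 0:
            raise ValueError("audio track is empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate


@dataclass(frozen=True)
class VocEvent:
    """One annotated utterance interval."""

    onset: float
    offset: float
    label: str = "protophone"
    coder: str = ""

    def __post_init__(self):
        if not self.offset > self.onset:
            raise ValueError(
                f"event offset ({self.offset}) must exceed onset ({self.onset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class AccChannel:
    """One sensor's timestamped 3-axis acceleration.

    ``gap_mask`` is True on samples that are missing (dropped packets,
    reconstructed grid points, non-finite readings) or were interpolated;
    such samples never drive results downstream.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    rate: float
    placement: Placement
    gap_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.t.size, dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        n = self.t.size
        if not (self.x.size == self.y.size == self.z.size == self.gap_mask.size == n):
            raise ValueError("AccChannel arrays must share one length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("AccChannel timestamps must be strictly increasing")
        valid = ~self.gap_mask
        for arr in (self.x, self.y, self.z):
            if not np.all(np.isfinite(arr[valid])):
                raise ValueError("non-finite samples outside the gap mask")

    def copy(self) -> "AccChannel":
        return AccChannel(
            t=self.t.copy(), x=self.x.copy(), y=self.y.copy(), z=self.z.copy(),
            rate=self.rate, placement=self.placement, gap_mask=self.gap_mask.copy(),
        )


@dataclass
class MagnitudeSeries:
    """Scalar acceleration magnitude on a uniform grid.

    ``mask`` is the union of gap and artifact masks; after the 1 Hz highpass
    the values lose their non-negativity (gravity/DC removed).
    """

    t: np.ndarray
    value: np.ndarray
    rate: float
    placement: Placement
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.t.size, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.t.size == self.value.size == self.mask.size):
            raise ValueError("MagnitudeSeries arrays must share one length")

    def copy(self) -> "MagnitudeSeries":
        return MagnitudeSeries(self.t.copy(), self.value.copy(), self.rate,
                               self.placement, self.mask.copy())


@dataclass
class Epoch:
    """One limb-side trace on the fixed epoch grid around one vocalisation.

    ``raw`` is filled at extraction; ``baselined`` after envelope baseline
    correction; ``envelope`` after the analytic-envelope step.
    """

    event_index: int
    onset: float
    placement: Placement
    raw: Optional[np.ndarray] = None
    baselined: Optional[np.ndarray] = None
    envelope: Optional[np.ndarray] = None
    excluded: bool = False
    reason: str = ""
    infant_id: str = ""
    time_point: Optional[int] = None
    overlaps_next: bool = False

    @property
    def limb(self) -> str:
        return self.placement.limb

    @property
    def side(self) -> str:
        return self.placement.side


@dataclass(frozen=True)
class WindowBounds:
    """Analysis windows relative to vocalisation onset (half-open [a, b)).

    The reference span (closed tail of the epoch) anchors the envelope
    baseline correction.
    """

    base: tuple = (-2.5, -0.9)
    pre: tuple = (-0.9, 0.0)
    during: tuple = (0.0, 0.9)
    reference: tuple = (3.5, 5.0)

    def window(self, name: str) -> tuple:
        return getattr(self, name)

    def sample_slice(self, name: str, rate: float = EPOCH_RATE) -> slice:
        """Half-open sample index range of a window on the epoch grid."""
        a, b = self.window(name)
        i0 = ONSET_INDEX + int(round(a * rate))
        i1 = ONSET_INDEX + int(round(b * rate))
        return slice(i0, i1)

    def reference_slice(self, rate: float = EPOCH_RATE) -> slice:
        a, b = self.reference
        i0 = ONSET_INDEX + int(round(a * rate))
        i1 = ONSET_INDEX + int(round(b * rate)) + 1  # closed at the epoch end
        return slice(i0, i1)


@dataclass
class SessionManifest:
    """Paths and placements for one recorded session."""

    infant_id: str
    time_point: int
    audio_path: str
    annotation_path: str
    acc_paths: dict  # Placement -> path
    nominal_rate: float = 60.0
    tier: str = "vocalisations"

    def __post_init__(self):
        if self.time_point not in TIME_POINTS:
            raise ValueError(
                f"time_point must be one of {TIME_POINTS}, got {self.time_point}"
            )
        for p in self.acc_paths:
            if p.wearer == "caregiver" and p.limb not in ("hand",):
                raise ValueError(
                    "caregiver sensors are used for synchronisation only; "
                    f"only hand placements are accepted, got {p.limb!r}"
                )

    def infant_channels(self) -> list:
        """Infant arm/leg placements, the ones analysed downstream."""
        return [p for p in self.acc_paths
                if p.wearer == "infant" and p.limb in LIMBS]

    def caregiver_hands(self) -> list:
        return [p for p in self.acc_paths
                if p.wearer == "caregiver" and p.limb == "hand"]

    def validate(self):
        """Check the infant limb coverage needed downstream."""
        have = {(p.limb, p.side) for p in self.infant_channels()}
        need = {(l, s) for l in LIMBS for s in SIDES}
        missing = need - have
        if missing:
            raise ValueError(f"manifest missing infant sensors: {sorted(missing)}")
        return self
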