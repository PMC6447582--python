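"""Core containers shared across the pipeline.

A recording session consists of uniformly sampled channels: mechanomyogram
(MMG) and surface electromyogram (EMG) at 1 kHz, and the three accelerometer
axes of a thigh-worn IMU at 50 Hz.  Squat activity is described as a sequence
of labelled contraction-phase segments (entering / held / exiting) expressed
as 0-based, half-open sample intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "ChannelKind",
    "ChannelRecording",
    "SquatPhaseSegment",
    "GroundTruth",
    "PHASES",
]

#: Contraction phases of one squat repetition, in temporal order.
PHASES = ("entering", "held", "exiting")


class ChannelKind(str, Enum):
    """Identity of a recorded channel."""

    MMG = "MMG"
    EMG = "EMG"
    ACCEL_X = "ACCEL_X"
    ACCEL_Y = "ACCEL_Y"
    ACCEL_Z = "ACCEL_Z"

    @property
    def is_accel(self) -> bool:
        return self.name.startswith("ACCEL")

    @property
    def is_muscle(self) -> bool:
        return self in (ChannelKind.MMG, ChannelKind.EMG)


@dataclass
class ChannelRecording:
    """One uniformly sampled signal.

    Parameters
    ----------
    samples : array-like of float
        The sample values (volts for MMG/EMG, m/s^2 for accelerometer axes).
    rate : float
        Sampling rate in Hz; must be positive.
    kind : ChannelKind
        Which physical channel this is.
    units : str
        Unit string carried through to file headers.
    """

    samples: np.ndarray
    rate: float
    kind: ChannelKind
    units: str = "V"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.kind = ChannelKind(self.kind)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("recording must be a non-empty 1-D sample array")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.rate

    def time(self) -> np.ndarray:
        """Time axis in seconds (sample i at i / rate)."""
        return np.arange(self.n) / self.rate

    def replace(self, samples: np.ndarray) -> "ChannelRecording":
        """Copy of this recording with new samples (rate/kind/units kept)."""
        return ChannelRecording(samples=np.asarray(samples, float),
                                rate=self.rate, kind=self.kind, units=self.units)


@dataclass(frozen=True)
class SquatPhaseSegment:
    """A labelled [start, stop) sample interval of one contraction phase."""

    rep_index: int
    phase: str
    start: int
    stop: int
    rate: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if not 0 <= self.start < self.stop:
            raise ValueError(
                f"require 0 <= start < stop, got [{self.start}, {self.stop})")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    @property
    def start_s(self) -> float:
        return self.start / self.rate

    @property
    def stop_s(self) -> float:
        return self.stop / self.rate

    @property
    def duration_s(self) -> float:
        return (self.stop - self.start) / self.rate

    def at_rate(self, rate: float) -> "SquatPhaseSegment":
        """Re-express the interval at another sampling rate (e.g. 50 Hz
        accelerometer indices mapped onto the 1 kHz muscle channels)."""
        f = rate / self.rate
        return SquatPhaseSegment(self.rep_index, self.phase,
                                 int(round(self.start * f)),
                                 int(round(self.stop * f)), rate)


def _check_segments(segments: Sequence[SquatPhaseSegment], n_samples: int) -> None:
    prev_stop = 0
    for seg in segments:
        if seg.start < prev_stop:
            raise ValueError("phase segments must be ordered and non-overlapping")
        if seg.stop > n_samples:
            raise ValueError("phase segment extends past the recording")
        prev_stop = seg.stop


@dataclass
class GroundTruth:
    """Generator-side annotation of a synthetic recording.

    Serves as the oracle for segmentation and feature tests: exact phase
    intervals, the knee-flexion angle of each held phase, the standing
    baseline interval, and the fatigue trends injected into each muscle
    channel (expressed as the % change between the first and last 10% of
    the hold, the statistic the analysis reports).
    """

    phase_segments: list[SquatPhaseSegment]
    knee_flexion_deg: list[float]
    baseline: tuple[int, int]
    n_samples: int
    rate: float
    injected_rms_change_pct: dict[str, float] = field(default_factory=dict)
    injected_mpf_change_pct: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_segments(self.phase_segments, self.n_samples)
        n_held = sum(1 for s in self.phase_segments if s.phase == "held")
        if len(self.knee_flexion_deg) != n_held:
            raise ValueError("one knee-flexion angle required per held phase")

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def segments_of(self, phase: str) -> list[SquatPhaseSegment]:
        return [s for s in self.phase_segments if s.phase == phase]

    @property
    def n_reps(self) -> int:
        return len(self.segments_of("held"))
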