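"""IMU-driven squat-phase segmentation.

Squat repetitions are located on the smoothed X-axis accelerometer: posture
transitions appear as gradient excursions, and a repetition is a negative
excursion (descent / entering), the quiet gap (held), then a positive
excursion (ascent / exiting).  The detection threshold is relative — 10% of
the recording's peak absolute gradient after subtracting the stationary
baseline gradient level — so segmentation is invariant to the accelerometer's
scale.  Knee flexion is estimated by comparing the gravity vector of a phase
against the standing baseline ("zeroing off" the sensor while standing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ChannelKind, ChannelRecording, GroundTruth, SquatPhaseSegment

log = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "Transition",
    "FlexionEstimate",
    "detect_transitions",
    "assemble_repetitions",
    "segment_repetitions",
    "isolate_hold",
    "estimate_flexion",
    "boundary_errors_s",
]


@dataclass
class SegmentationConfig:
    """Tunables of the gradient-threshold detector.

    ``gradient_threshold_frac``: transition opens where the baseline-corrected
    |gradient| exceeds this fraction of its peak over the recording (0.10 —
    the "10% increase and decrease in gradient" rule).
    ``hysteresis_frac``: the interval extends until |gradient| falls below
    this fraction of the peak, preventing chatter at the crossing.
    """

    gradient_threshold_frac: float = 0.10
    hysteresis_frac: float = 0.05
    min_held_s: float = 1.0
    min_stationary_s: float = 2.0
    smoothing_window_s: float = 0.5
    min_transition_s: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.gradient_threshold_frac < 1:
            raise ValueError("gradient_threshold_frac must be in (0, 1)")
        if not 0 < self.hysteresis_frac < self.gradient_threshold_frac:
            raise ValueError("hysteresis_frac must be in (0, threshold)")
        for name in ("min_held_s", "min_stationary_s", "smoothing_window_s",
                     "min_transition_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Transition:
    """A maximal interval of supra-threshold gradient; sign −1 = descent."""

    start: int
    stop: int
    sign: int
    rate: float

    @property
    def start_s(self) -> float:
        return self.start / self.rate

    @property
    def stop_s(self) -> float:
        return self.stop / self.rate

    @property
    def duration_s(self) -> float:
        return (self.stop - self.start) / self.rate


@dataclass(frozen=True)
class FlexionEstimate:
    """Knee-flexion angle from the rotation of the mean gravity vector."""

    angle_deg: float
    baseline_vector: tuple[float, float, float]
    phase_vector: tuple[float, float, float]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_transitions(accel_x: ChannelRecording,
                       cfg: SegmentationConfig | None = None) -> list[Transition]:
    """Find posture transitions on a smoothed X-axis accelerometer trace.

    The gradient is the first difference of the trace scaled by the sample
    rate.  Its level over the initial stationary window (median of the first
    ``min_stationary_s``) is subtracted; intervals open where the corrected
    |gradient| exceeds ``gradient_threshold_frac`` x peak, are extended while
    it stays above ``hysteresis_frac`` x peak, and are kept if at least
    ``min_transition_s`` long.  A constant trace yields an empty list.
    """
    cfg = cfg or SegmentationConfig()
    x = accel_x.samples
    rate = accel_x.rate
    n_base = int(round(cfg.min_stationary_s * rate))
    if x.size <= n_base + 1:
        raise ValueError("recording shorter than the stationary baseline period")

    g = np.diff(x) * rate
    d = g - np.median(g[:n_base])
    peak = float(np.max(np.abs(d)))
    if peak == 0.0:
        return []
    above_hi = np.abs(d) > cfg.gradient_threshold_frac * peak
    above_lo = np.abs(d) > cfg.hysteresis_frac * peak

    out: list[Transition] = []
    for a, b in _runs(above_lo):
        if not above_hi[a:b].any():
            continue
        if (b - a + 1) / rate < cfg.min_transition_s:
            continue
        sign = 1 if float(np.mean(d[a:b])) > 0 else -1
        # diff index i sits between samples i and i+1
        out.append(Transition(a, b + 1, sign, rate))
    return out


def assemble_repetitions(transitions: list[Transition],
                         cfg: SegmentationConfig | None = None) -> list[SquatPhaseSegment]:
    """Pair descent/ascent transitions into entering/held/exiting triples.

    Each negative transition is matched with the next positive one; the gap
    between them becomes the held phase when it lasts at least
    ``min_held_s``.  Unpaired or malformed transitions are dropped with a
    logged warning.
    """
    cfg = cfg or SegmentationConfig()
    segments: list[SquatPhaseSegment] = []
    rep = 0
    i = 0
    while i < len(transitions):
        neg = transitions[i]
        if neg.sign >= 0:
            log.warning("unpaired ascent transition at %.2f s dropped", neg.start_s)
            i += 1
            continue
        if i + 1 < len(transitions) and transitions[i + 1].sign < 0:
            log.warning("consecutive descent transitions; dropping the one at %.2f s",
                        neg.start_s)
            i += 1
            continue
        if i + 1 >= len(transitions):
            log.warning("descent at %.2f s has no matching ascent; dropped", neg.start_s)
            break
        pos = transitions[i + 1]
        held_len_s = (pos.start - neg.stop) / neg.rate
        if held_len_s < cfg.min_held_s:
            log.warning("gap of %.2f s between transitions at %.2f s is below "
                        "min_held_s; pair dropped", held_len_s, neg.start_s)
            i += 2
            continue
        segments.append(SquatPhaseSegment(rep, "entering", neg.start, neg.stop, neg.rate))
        segments.append(SquatPhaseSegment(rep, "held", neg.stop, pos.start, neg.rate))
        segments.append(SquatPhaseSegment(rep, "exiting", pos.start, pos.stop, pos.rate))
        rep += 1
        i += 2
    return segments


def segment_repetitions(accel_x: ChannelRecording,
                        cfg: SegmentationConfig | None = None) -> list[SquatPhaseSegment]:
    """Convenience: detect transitions and assemble repetitions in one call."""
    return assemble_repetitions(detect_transitions(accel_x, cfg), cfg)


def isolate_hold(accel_x: ChannelRecording,
                 cfg: SegmentationConfig | None = None) -> SquatPhaseSegment:
    """Isolate the single held contraction of a wall-squat recording.

    Returns the interval between the end of the first descent and the start
    of the last ascent.  Raises if either transition is missing or the hold
    is shorter than ``min_held_s`` (a hold of exactly ``min_held_s`` is
    accepted).
    """
    cfg = cfg or SegmentationConfig()
    transitions = detect_transitions(accel_x, cfg)
    negs = [t for t in transitions if t.sign < 0]
    poss = [t for t in transitions if t.sign > 0]
    if not negs or not poss:
        raise ValueError("wall-squat recording must contain a descent and an ascent")
    start, stop = negs[0].stop, poss[-1].start
    if (stop - start) / accel_x.rate < cfg.min_held_s:
        raise ValueError("held period shorter than min_held_s")
    return SquatPhaseSegment(0, "held", start, stop, accel_x.rate)


def estimate_flexion(accel_xyz: tuple[ChannelRecording, ChannelRecording, ChannelRecording],
                     baseline: tuple[int, int],
                     phase: tuple[int, int],
                     min_magnitude_frac_g: float = 0.5) -> FlexionEstimate:
    """Knee flexion as the angle between mean gravity vectors.

    ``baseline`` and ``phase`` are [start, stop) sample intervals over which
    the three axes are averaged; both postures must be quasi-static (mean
    vector magnitude at least ``min_magnitude_frac_g`` x g), otherwise the
    reading is motion-dominated and an error is raised.
    """
    g0 = 9.81

    def mean_vec(interval: tuple[int, int]) -> np.ndarray:
        a, b = interval
        n = accel_xyz[0].n
        if not 0 <= a < b <= n:
            raise ValueError(f"interval [{a}, {b}) outside recording of {n} samples")
        return np.array([float(np.mean(ch.samples[a:b])) for ch in accel_xyz])

    v0, v1 = mean_vec(baseline), mean_vec(phase)
    m0, m1 = np.linalg.norm(v0), np.linalg.norm(v1)
    if m0 < min_magnitude_frac_g * g0 or m1 < min_magnitude_frac_g * g0:
        raise ValueError("mean acceleration below 0.5 g; posture not quasi-static")
    cosang = float(np.clip(np.dot(v0, v1) / (m0 * m1), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    return FlexionEstimate(angle, tuple(v0), tuple(v1))


def boundary_errors_s(detected: list[SquatPhaseSegment],
                      truth: GroundTruth | list[SquatPhaseSegment]) -> np.ndarray:
    """Absolute start/stop errors (s) of detected segments vs. a reference.

    Segments are matched by (rep_index, phase); unmatched reference segments
    are ignored, so pair this with an explicit repetition-count check.
    """
    ref = truth.phase_segments if isinstance(truth, GroundTruth) else truth
    ref_map = {(s.rep_index, s.phase): s for s in ref}
    errs: list[float] = []
    for s in detected:
        r = ref_map.get((s.rep_index, s.phase))
        if r is None:
            continue
        errs.append(abs(s.start_s - r.start_s))
        errs.append(abs(s.stop_s - r.stop_s))
    return np.asarray(errs)
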