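"""Synthetic session generator.

Emulates the three-stage squat protocol used in wearable muscle-fatigue
studies: five 5-s unloaded squats (pre-exertion), a wall squat held to
exhaustion, and five more squats after a recovery period (post-exertion).

Three signal families are produced with exact ground-truth annotations:

* **Accelerometer (50 Hz).**  The X axis lies along the thigh, so standing
  reads +g and squatting to knee flexion theta reads g*cos(theta); descent is
  a smooth raised-cosine transition and therefore a negative X gradient.
* **MMG (1 kHz).**  Band-limited Gaussian noise with its power concentrated
  around 7-8 Hz, the mechanical resonance range reported for the quadriceps.
* **EMG (1 kHz).**  Same construction with an 80-90 Hz spectral peak.

Muscle channels are built by shaping white noise with a resonant band-pass
filter (centre = peak frequency, bandwidth configurable), band-limiting to
the channel band, equalising the short-time amplitude, and imposing an
explicit RMS envelope: rest level x per-phase gain, with an optional linear
fatigue ramp over each held phase.  MPF drift is injected by sweeping the
shaping filter's centre frequency linearly across the hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.stats import truncnorm

from .core import ChannelKind, ChannelRecording, GroundTruth, SquatPhaseSegment

__all__ = [
    "ProtocolSpec",
    "SignalModelSpec",
    "slope_for_pct_change",
    "generate_accel_trace",
    "generate_muscle_signal",
    "generate_session",
    "draw_hold_durations",
    "GRAVITY",
]

GRAVITY = 9.81  # m/s^2

#: duration (s) of stationary signal appended after the last repetition
_TRAILING_S = 3.0
#: pre-roll discarded after IIR shaping so filter transients never leak in
_PREROLL_S = 2.0
#: block length (s) used when sweeping the shaping filter's centre frequency
_SWEEP_BLOCK_S = 0.25
#: window (s) of the short-time amplitude equaliser
_EQ_WINDOW_S = 0.4
#: block (s) of the exact RMS normalisation stage
_EQ_BLOCK_S = 0.5
#: window (s) used to soften RMS-envelope steps at phase boundaries
_ENV_SMOOTH_S = 0.05


@dataclass
class ProtocolSpec:
    """Timing and posture of the squat protocol.

    Defaults reproduce the study conditions: five 5-s squats with 5-s pauses
    in the pre and post stages, and a single wall squat whose duration is a
    free parameter (group mean 88.5 s).  Flexion defaults are the measured
    group angles (64.11 deg pre, 64.25 deg post, 78.44 deg wall squat) rather
    than the instructed 75 deg / 90 deg targets.
    """

    n_reps_pre: int = 5
    n_reps_post: int = 5
    squat_hold_s: float = 5.0
    inter_squat_pause_s: float = 5.0
    wall_squat_duration_s: float = 88.5
    transition_duration_s: float = 1.0
    standing_baseline_s: float = 5.0
    pre_flexion_deg: float = 64.11
    post_flexion_deg: float = 64.25
    wall_flexion_deg: float = 78.44

    def __post_init__(self) -> None:
        for name in ("squat_hold_s", "inter_squat_pause_s",
                     "wall_squat_duration_s", "transition_duration_s",
                     "standing_baseline_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_reps_pre < 1 or self.n_reps_post < 1:
            raise ValueError("need at least one repetition per stage")
        if self.wall_squat_duration_s < 10:
            raise ValueError("wall squat must last at least 10 s")


def slope_for_pct_change(pct: float) -> float:
    """Invert the first/last-10% observable to a linear envelope slope.

    The fatigue ramp multiplies the envelope by ``1 + s*u`` with ``u`` the
    normalized hold time.  The trend statistic the analysis reports is the
    percent change between the mean of the first and of the last 10% of the
    hold, which for that ramp is ``100 * 0.9*s / (1 + 0.05*s)``.  This helper
    returns the ``s`` that makes the observable equal ``pct``.
    """
    f = pct / 100.0
    s = f / (0.9 - 0.05 * f)
    return s


def pct_change_for_slope(s: float) -> float:
    """Forward map of :func:`slope_for_pct_change`."""
    return 100.0 * 0.9 * s / (1.0 + 0.05 * s)


@dataclass
class SignalModelSpec:
    """Spectral and amplitude model of one muscle channel.

    ``fatigue_rms_slope`` / ``fatigue_mpf_slope`` are fractional changes per
    unit normalized hold time (envelope and centre frequency vary as
    ``1 + slope*u``); :func:`slope_for_pct_change` converts a target
    first/last-10% percent change into a slope.
    """

    band_hz: tuple[float, float]
    peak_hz: float
    bandwidth_hz: float
    rest_rms: float
    phase_gain: dict[str, float]
    fatigue_rms_slope: float = 0.0
    fatigue_mpf_slope: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        low, high = self.band_hz
        if not 0 < low < high:
            raise ValueError("band must satisfy 0 < low < high")
        if not low <= self.peak_hz <= high:
            raise ValueError("peak frequency must lie inside the band")
        if self.bandwidth_hz <= 0 or self.rest_rms <= 0:
            raise ValueError("bandwidth and rest RMS must be positive")
        if any(g <= 0 for g in self.phase_gain.values()):
            raise ValueError("phase gains must be positive")

    @classmethod
    def mmg_default(cls, **overrides) -> "SignalModelSpec":
        """Mechanomyogram model: 7.5 Hz peak, rest + phase gains sized so
        phase-level RMS lands near the observed 0.19-0.26 V range, and
        fatigue ramps matching the reported +29.35% RMS / -5.98% MPF hold
        trends."""
        kw = dict(band_hz=(2.0, 100.0), peak_hz=7.5, bandwidth_hz=2.0,
                  rest_rms=0.05,
                  phase_gain={"entering": 5.2, "held": 3.8, "exiting": 4.0},
                  fatigue_rms_slope=slope_for_pct_change(29.35),
                  fatigue_mpf_slope=slope_for_pct_change(-5.98))
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def emg_default(cls, **overrides) -> "SignalModelSpec":
        """Surface-EMG model: 85 Hz peak (hardware-amplified scale), fatigue
        ramps matching the reported +15.20% RMS / -18.07% MPF hold trends."""
        kw = dict(band_hz=(10.0, 495.0), peak_hz=85.0, bandwidth_hz=30.0,
                  rest_rms=0.08,
                  phase_gain={"entering": 4.75, "held": 5.75, "exiting": 5.0},
                  fatigue_rms_slope=slope_for_pct_change(15.20),
                  fatigue_mpf_slope=slope_for_pct_change(-18.07))
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def default_for(cls, channel: ChannelKind | str, **overrides) -> "SignalModelSpec":
        channel = ChannelKind(channel)
        if channel is ChannelKind.MMG:
            return cls.mmg_default(**overrides)
        if channel is ChannelKind.EMG:
            return cls.emg_default(**overrides)
        raise ValueError(f"no muscle-signal model for channel {channel}")


# ---------------------------------------------------------------------------
# accelerometer trace
# ---------------------------------------------------------------------------

def _raised_cosine(n: int) -> np.ndarray:
    """Smooth monotone 0 -> 1 ramp over n samples (half-cosine)."""
    u = np.linspace(0.0, 1.0, n, endpoint=False)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def _build_angle_profile(reps: Sequence[tuple[float, float]],
                         protocol: ProtocolSpec,
                         rate: float) -> tuple[np.ndarray, list[SquatPhaseSegment], list[float], tuple[int, int]]:
    """Knee-flexion angle (deg) per sample plus exact phase annotations."""
    t_trans = int(round(protocol.transition_duration_s * rate))
    n_base = int(round(protocol.standing_baseline_s * rate))
    n_pause = int(round(protocol.inter_squat_pause_s * rate))
    n_trail = int(round(_TRAILING_S * rate))
    if t_trans < 2:
        raise ValueError("transition shorter than two samples; raise the rate")

    chunks: list[np.ndarray] = [np.zeros(n_base)]
    segments: list[SquatPhaseSegment] = []
    flexions: list[float] = []
    pos = n_base
    ramp = _raised_cosine(t_trans)
    for rep, (hold_s, flex) in enumerate(reps):
        n_hold = int(round(hold_s * rate))
        segments.append(SquatPhaseSegment(rep, "entering", pos, pos + t_trans, rate))
        chunks.append(flex * ramp)
        pos += t_trans
        segments.append(SquatPhaseSegment(rep, "held", pos, pos + n_hold, rate))
        chunks.append(np.full(n_hold, flex))
        pos += n_hold
        segments.append(SquatPhaseSegment(rep, "exiting", pos, pos + t_trans, rate))
        chunks.append(flex * (1.0 - ramp))
        pos += t_trans
        flexions.append(flex)
        n_gap = n_pause if rep < len(reps) - 1 else n_trail
        chunks.append(np.zeros(n_gap))
        pos += n_gap
    angle = np.concatenate(chunks)
    return angle, segments, flexions, (0, n_base)


def generate_accel_trace(protocol: ProtocolSpec,
                         sample_rate: float = 50.0,
                         seed: int | np.random.Generator | None = 0,
                         *,
                         stage: str = "pre",
                         noise_std: float = 0.15,
                         ) -> tuple[ChannelRecording, ChannelRecording, ChannelRecording, GroundTruth]:
    """Generate the triaxial accelerometer trace for one protocol stage.

    Parameters
    ----------
    stage : {"pre", "hold", "post"}
        Pre/post stages produce the repeated 5-s squats; "hold" produces the
        single wall squat of ``protocol.wall_squat_duration_s``.
    noise_std : float
        Additive Gaussian sensor noise, m/s^2.  The ADXL345-class MEMS parts
        used in thigh-worn IMUs show ~0.1-0.2 m/s^2 broadband noise at 50 Hz.

    Returns ``(accel_x, accel_y, accel_z, ground_truth)``.  Gravity rotates in
    the X-Y plane with the knee-flexion angle, so descent gives a negative
    X-axis gradient.
    """
    if not sample_rate > 0:
        raise ValueError("sample rate must be positive")
    if stage not in ("pre", "hold", "post"):
        raise ValueError(f"unknown stage {stage!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if stage == "hold":
        reps = [(protocol.wall_squat_duration_s, protocol.wall_flexion_deg)]
    else:
        flex = protocol.pre_flexion_deg if stage == "pre" else protocol.post_flexion_deg
        n_reps = protocol.n_reps_pre if stage == "pre" else protocol.n_reps_post
        reps = [(protocol.squat_hold_s, flex)] * n_reps

    angle, segments, flexions, baseline = _build_angle_profile(reps, protocol, sample_rate)
    theta = np.deg2rad(angle)
    n = angle.size
    ax = GRAVITY * np.cos(theta) + rng.normal(0.0, noise_std, n)
    ay = GRAVITY * np.sin(theta) + rng.normal(0.0, noise_std, n)
    az = rng.normal(0.0, noise_std, n)

    truth = GroundTruth(phase_segments=segments, knee_flexion_deg=flexions,
                        baseline=baseline, n_samples=n, rate=sample_rate)
    mk = lambda x, kind: ChannelRecording(x, sample_rate, kind, units="m/s^2")
    return (mk(ax, ChannelKind.ACCEL_X), mk(ay, ChannelKind.ACCEL_Y),
            mk(az, ChannelKind.ACCEL_Z), truth)


# ---------------------------------------------------------------------------
# muscle channels
# ---------------------------------------------------------------------------

def _shaping_sos(centre: float, bandwidth: float, rate: float) -> np.ndarray:
    low = max(centre - bandwidth / 2.0, 0.1)
    high = min(centre + bandwidth / 2.0, 0.499 * rate)
    return signal.butter(2, [low, high], btype="bandpass", fs=rate, output="sos")


def _moving_mean(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with a shrinking window at the edges."""
    n = max(int(n), 1)
    c = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(x.size)
    h_lo = n // 2
    h_hi = n - 1 - h_lo
    lo = np.maximum(idx - h_lo, 0)
    hi = np.minimum(idx + h_hi + 1, x.size)
    return (c[hi] - c[lo]) / (hi - lo)


def _centre_profile(model: SignalModelSpec, truth: GroundTruth, n: int,
                    rate: float) -> np.ndarray:
    """Per-sample shaping-filter centre frequency (linear sweep over holds)."""
    centre = np.full(n, model.peak_hz)
    if model.fatigue_mpf_slope == 0.0:
        return centre
    scale = rate / truth.rate
    for seg in truth.segments_of("held"):
        a, b = int(round(seg.start * scale)), int(round(seg.stop * scale))
        a, b = max(a, 0), min(b, n)
        if b <= a:
            continue
        u = (np.arange(a, b) - a + 0.5) / (b - a)
        centre[a:b] = model.peak_hz * (1.0 + model.fatigue_mpf_slope * u)
    return centre


def _target_envelope(model: SignalModelSpec, truth: GroundTruth, n: int,
                     rate: float) -> np.ndarray:
    env = np.full(n, model.rest_rms)
    scale = rate / truth.rate
    for seg in truth.phase_segments:
        a, b = int(round(seg.start * scale)), int(round(seg.stop * scale))
        a, b = max(a, 0), min(b, n)
        if b <= a:
            continue
        gain = model.phase_gain.get(seg.phase, 1.0)
        level = np.full(b - a, model.rest_rms * gain)
        if seg.phase == "held" and model.fatigue_rms_slope != 0.0:
            u = (np.arange(b - a) + 0.5) / (b - a)
            level *= 1.0 + model.fatigue_rms_slope * u
        env[a:b] = level
    return _moving_mean(env, int(round(_ENV_SMOOTH_S * rate)))


def generate_muscle_signal(model: SignalModelSpec,
                           truth: GroundTruth,
                           channel: ChannelKind | str,
                           sample_rate: float = 1000.0,
                           seed: int | np.random.Generator | None = None,
                           ) -> ChannelRecording:
    """Generate one MMG or EMG channel consistent with a ground truth.

    White Gaussian noise is shaped by a resonant band filter whose centre
    frequency follows :func:`_centre_profile` (constant at the peak, swept
    linearly over held phases when an MPF drift is configured), band-limited
    to the channel band, amplitude-equalised over a 0.4 s window, and scaled
    by the target RMS envelope.  The envelope is therefore imposed exactly at
    the equaliser's time scale; residual sub-window energy fluctuation is the
    only amplitude noise left, which mimics the small window-to-window RMS
    scatter of real recordings.
    """
    channel = ChannelKind(channel)
    if not channel.is_muscle:
        raise ValueError("channel must be MMG or EMG")
    if not truth.phase_segments:
        raise ValueError("ground truth contains no phase segments")
    low, high = model.band_hz
    if not low <= model.peak_hz <= high:
        raise ValueError("peak frequency outside the channel band")
    if seed is None:
        seed = model.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = int(round(truth.duration_s * sample_rate))
    pre = int(round(_PREROLL_S * sample_rate))
    white = rng.standard_normal(n + pre)

    centre = np.concatenate([np.full(pre, model.peak_hz),
                             _centre_profile(model, truth, n, sample_rate)])
    # blockwise time-varying shaping; filter state carried across blocks
    block = int(round(_SWEEP_BLOCK_S * sample_rate))
    shaped = np.empty_like(white)
    zi = None
    sos_cache: dict[float, np.ndarray] = {}
    pos = 0
    while pos < white.size:
        stop = min(pos + block, white.size)
        c = round(float(np.mean(centre[pos:stop])), 4)
        sos = sos_cache.get(c)
        if sos is None:
            sos = sos_cache[c] = _shaping_sos(c, model.bandwidth_hz, sample_rate)
        if zi is None:
            zi = np.zeros((sos.shape[0], 2))
        shaped[pos:stop], zi = signal.sosfilt(sos, white[pos:stop], zi=zi)
        pos = stop

    # channel band limit (sensor passband), then drop the warm-up pre-roll
    high_c = min(high, 0.495 * sample_rate)  # keep below Nyquist
    band_sos = signal.butter(4, [low, high_c], btype="bandpass",
                             fs=sample_rate, output="sos")
    shaped = signal.sosfilt(band_sos, shaped)[pre:]

    # amplitude equalisation: a smooth local-RMS pass removes slow envelope
    # wander, then exact per-block normalisation pins the block RMS to one.
    # Blocks restart at every phase boundary so each phase segment carries
    # its target RMS exactly; residual sub-block fluctuation is the only
    # amplitude noise left.
    local = np.sqrt(_moving_mean(shaped ** 2, int(round(_EQ_WINDOW_S * sample_rate))))
    shaped = shaped / np.maximum(local, 1e-12)
    blk = int(round(_EQ_BLOCK_S * sample_rate))
    scale = sample_rate / truth.rate
    edges = {0, n}
    for seg in truth.phase_segments:
        edges.add(min(max(int(round(seg.start * scale)), 0), n))
        edges.add(min(max(int(round(seg.stop * scale)), 0), n))
    edges = sorted(edges)
    for lo, hi in zip(edges, edges[1:]):
        for a in range(lo, hi, blk):
            b = min(a + blk, hi)
            r = np.sqrt(np.mean(shaped[a:b] ** 2))
            if r > 0:
                shaped[a:b] /= r
    shaped *= _target_envelope(model, truth, n, sample_rate)
    return ChannelRecording(shaped, sample_rate, channel, units="V")


# ---------------------------------------------------------------------------
# full sessions
# ---------------------------------------------------------------------------

def draw_hold_durations(n: int,
                        rng: np.random.Generator,
                        mean_s: float = 88.5,
                        sd_s: float = 28.48,
                        min_s: float = 20.0) -> np.ndarray:
    """Wall-squat endurance times: truncated normal, floor at ``min_s``."""
    a = (min_s - mean_s) / sd_s
    return truncnorm.rvs(a, np.inf, loc=mean_s, scale=sd_s, size=n,
                         random_state=rng)


def _participant_rng(master_seed: int, participant: int, stream: int) -> np.random.Generator:
    """Deterministic per-participant, per-stream generator.

    Uses ``SeedSequence([master_seed, participant, stream])`` — a fixed
    counter scheme, stable across platforms and runs.
    """
    return np.random.default_rng(np.random.SeedSequence([master_seed, participant, stream]))


_STAGES = ("pre", "hold", "post")


def generate_session(protocol: ProtocolSpec | None = None,
                     mmg_model: SignalModelSpec | None = None,
                     emg_model: SignalModelSpec | None = None,
                     n_participants: int = 5,
                     seed: int = 0,
                     *,
                     hold_mean_s: float = 88.5,
                     hold_sd_s: float = 28.48,
                     hold_min_s: float = 20.0,
                     post_rms_scale: float = 1.0,
                     accel_noise_std: float = 0.15,
                     muscle_rate: float = 1000.0,
                     accel_rate: float = 50.0,
                     stages: tuple[str, ...] = _STAGES) -> dict:
    """Generate a complete multi-participant session bundle.

    Each participant gets three stages (pre / hold / post), each with MMG,
    EMG, the three accelerometer axes and a :class:`GroundTruth`.  Stage-2
    hold durations are drawn per participant from the truncated-normal
    endurance distribution.  ``post_rms_scale`` multiplies the post-stage
    muscle phase gains, allowing a controlled pre/post amplitude difference
    (default 1.0: no injected pre/post change).

    Fatigue ramps apply only to the wall-squat hold; the 5-s squats of the
    pre/post stages are generated trend-free.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    protocol = protocol or ProtocolSpec()
    mmg_model = mmg_model or SignalModelSpec.mmg_default()
    emg_model = emg_model or SignalModelSpec.emg_default()

    bundle: dict = {"seed": seed, "protocol": protocol, "participants": []}
    for p in range(n_participants):
        hold_s = float(draw_hold_durations(
            1, _participant_rng(seed, p, 0), hold_mean_s, hold_sd_s, hold_min_s)[0])
        proto_p = replace(protocol, wall_squat_duration_s=hold_s)
        part: dict = {"id": f"P{p + 1:02d}", "stages": {}}
        for si, stage in enumerate(_STAGES):
            if stage not in stages:
                continue
            ax, ay, az, truth = generate_accel_trace(
                proto_p, accel_rate, _participant_rng(seed, p, 10 + si),
                stage=stage, noise_std=accel_noise_std)
            stage_models = {}
            for ci, (kind, model) in enumerate(
                    ((ChannelKind.MMG, mmg_model), (ChannelKind.EMG, emg_model))):
                m = model
                if stage != "hold":
                    m = replace(m, fatigue_rms_slope=0.0, fatigue_mpf_slope=0.0)
                if stage == "post" and post_rms_scale != 1.0:
                    m = replace(m, phase_gain={k: g * post_rms_scale
                                               for k, g in m.phase_gain.items()})
                rec = generate_muscle_signal(
                    m, truth, kind, muscle_rate,
                    _participant_rng(seed, p, 100 + 10 * si + ci))
                stage_models[kind.value] = rec
                if stage == "hold":
                    truth.injected_rms_change_pct[kind.value] = \
                        pct_change_for_slope(m.fatigue_rms_slope)
                    truth.injected_mpf_change_pct[kind.value] = \
                        pct_change_for_slope(m.fatigue_mpf_slope)
            part["stages"][stage] = {
                "ACCEL_X": ax, "ACCEL_Y": ay, "ACCEL_Z": az,
                "truth": truth, **stage_models}
        bundle["participants"].append(part)
    return bundle
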