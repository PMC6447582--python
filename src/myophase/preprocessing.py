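"""Offline filtering of raw channels.

MMG is band-pass filtered 2-100 Hz and EMG 10-500 Hz with a 5th-order
Butterworth; accelerometer axes are smoothed with a centered moving average.
Filtering defaults to zero-phase (forward-backward) application so phase
timing stays aligned with the IMU segmentation; the effective magnitude
response is then the squared single-pass response.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .core import ChannelKind, ChannelRecording
from .synthetic import _moving_mean as _moving_mean_impl

log = logging.getLogger(__name__)

__all__ = ["bandpass", "smooth_accel", "default_band", "DEFAULT_BANDS",
           "moving_mean"]

#: per-channel band-pass edges in Hz
DEFAULT_BANDS: dict[ChannelKind, tuple[float, float]] = {
    ChannelKind.MMG: (2.0, 100.0),
    ChannelKind.EMG: (10.0, 500.0),
}

#: upper cutoffs at/above Nyquist are clipped to this fraction of it
NYQUIST_CLIP = 0.99


def default_band(kind: ChannelKind | str, rate: float | None = None) -> tuple[float, float]:
    """Band-pass edges for a channel kind, with the upper edge clipped below
    Nyquist when a rate is given (EMG's 500 Hz edge is not realisable at
    1 kHz sampling and becomes 495 Hz)."""
    low, high = DEFAULT_BANDS[ChannelKind(kind)]
    if rate is not None:
        high = min(high, NYQUIST_CLIP * rate / 2.0)
    return low, high


def bandpass(rec: ChannelRecording,
             low: float | None = None,
             high: float | None = None,
             order: int = 5,
             zero_phase: bool = True) -> ChannelRecording:
    """Butterworth band-pass a muscle channel.

    ``low``/``high`` default to the channel's standard band.  An upper cutoff
    at or above Nyquist is clipped to 99% of Nyquist with a logged warning.
    ``zero_phase=True`` applies the filter forward and backward
    (``sosfiltfilt``), doubling the effective order but leaving timing
    undistorted; set it to False for a single causal pass.
    """
    nyq = rec.rate / 2.0
    if low is None or high is None:
        dlow, dhigh = DEFAULT_BANDS.get(rec.kind, (None, None))
        low = dlow if low is None else low
        high = dhigh if high is None else high
    if low is None or high is None:
        raise ValueError(f"no default band for channel {rec.kind}; pass low/high")
    if high >= nyq:
        clipped = NYQUIST_CLIP * nyq
        log.warning("upper cutoff %.6g Hz >= Nyquist (%.6g Hz); clipping to %.6g Hz",
                    high, nyq, clipped)
        high = clipped
    if not 0 < low < high:
        raise ValueError(f"require 0 < low < high < Nyquist, got ({low}, {high})")
    if order < 1:
        raise ValueError("filter order must be >= 1")

    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.rate,
                        output="sos")
    if zero_phase:
        y = signal.sosfiltfilt(sos, rec.samples)
    else:
        y = signal.sosfilt(sos, rec.samples)
    return rec.replace(y)


def moving_mean(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average of ``x`` over ``n`` samples; the window
    shrinks at the edges instead of padding, so no samples are fabricated."""
    if n < 1:
        raise ValueError("window must cover at least one sample")
    return _moving_mean_impl(np.asarray(x, float), n)


def smooth_accel(rec: ChannelRecording, window_s: float = 0.5) -> ChannelRecording:
    """Moving-average smoothing of an accelerometer axis.

    The default 0.5 s window (25 samples at 50 Hz) suppresses sensor noise
    while preserving the ~1 s posture transitions the segmentation relies on.
    """
    if not rec.kind.is_accel:
        raise ValueError(f"smooth_accel expects an accelerometer axis, got {rec.kind}")
    n = int(round(window_s * rec.rate))
    if n < 1:
        raise ValueError("smoothing window shorter than one sample")
    return rec.replace(moving_mean(rec.samples, n))
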