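"""Amplitude and frequency features of muscle activity.

Two scalar features describe each analysis window: the root-mean-square
amplitude (RMS, a proxy for contraction intensity) and the mean power
frequency (MPF), the power-weighted mean of the spectrum, which shifts with
fatigue and motor-unit recruitment.  Features are computed per contraction
phase and repetition (pre/post stages) or per 1-s non-overlapping window of
the wall-squat hold (exertion stage), then aggregated across repetitions and
participants.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .core import ChannelRecording, SquatPhaseSegment
from .preprocessing import default_band

log = logging.getLogger(__name__)

__all__ = [
    "rms",
    "mpf",
    "phase_features",
    "phase_means",
    "hold_series",
    "group_phase_average",
    "group_hold_average",
    "normalized_grid",
]

#: phase segments shorter than this are flagged missing rather than analysed
MIN_SEGMENT_S = 0.25
#: segments longer than this use Welch averaging (1-s sub-windows, 50% overlap)
WELCH_THRESHOLD_S = 2.0


def rms(samples: Sequence[float] | np.ndarray) -> float:
    """Root mean square: sqrt(mean(x^2)).  Errors on empty input."""
    x = np.asarray(samples, float)
    if x.size == 0:
        raise ValueError("rms of empty input")
    return float(np.sqrt(np.mean(x ** 2)))


def mpf(samples: Sequence[float] | np.ndarray, rate: float,
        band: tuple[float, float]) -> float:
    """Mean power frequency: spectral centroid over ``band``.

    The PSD comes from a Hann-windowed periodogram for windows up to 2 s and
    from Welch's method (1-s segments, 50% overlap) for longer ones, which
    stabilises phase-level estimates.  Only PSD bins inside ``band`` enter
    the centroid; zero in-band power is an error.
    """
    x = np.asarray(samples, float)
    low, high = band
    if not 0 <= low < high <= rate / 2.0:
        raise ValueError(f"band ({low}, {high}) must lie within (0, Nyquist)")
    if x.size < 2:
        raise ValueError("mpf needs at least two samples")
    if x.size / rate > WELCH_THRESHOLD_S:
        nper = min(int(rate), x.size)
        f, p = signal.welch(x, fs=rate, window="hann", nperseg=nper,
                            noverlap=nper // 2)
    else:
        f, p = signal.periodogram(x, fs=rate, window="hann")
    sel = (f >= low) & (f <= high)
    total = float(np.sum(p[sel]))
    if total <= 0.0:
        raise ValueError("no in-band power; cannot compute MPF")
    return float(np.sum(f[sel] * p[sel]) / total)


def _band_for(rec: ChannelRecording,
              band: tuple[float, float] | None) -> tuple[float, float]:
    return band if band is not None else default_band(rec.kind, rec.rate)


def phase_features(rec: ChannelRecording,
                   segments: Sequence[SquatPhaseSegment],
                   band: tuple[float, float] | None = None) -> pd.DataFrame:
    """RMS and MPF of one band-filtered muscle channel per phase segment.

    ``segments`` may be at the accelerometer rate; they are mapped onto the
    recording's rate.  Segments shorter than ``MIN_SEGMENT_S`` produce a row
    with NaN features and ``missing=True`` (logged), never an imputed value.

    Returns a tidy frame with columns phase, rep, rms, mpf, missing.
    """
    band = _band_for(rec, band)
    rows = []
    for seg in segments:
        s = seg if seg.rate == rec.rate else seg.at_rate(rec.rate)
        stop = min(s.stop, rec.n)
        if stop - s.start < MIN_SEGMENT_S * rec.rate:
            log.warning("segment rep=%d phase=%s shorter than %.2f s; flagged missing",
                        seg.rep_index, seg.phase, MIN_SEGMENT_S)
            rows.append((seg.phase, seg.rep_index, np.nan, np.nan, True))
            continue
        x = rec.samples[s.start:stop]
        rows.append((seg.phase, seg.rep_index, rms(x), mpf(x, rec.rate, band), False))
    return pd.DataFrame(rows, columns=["phase", "rep", "rms", "mpf", "missing"])


def phase_means(features: pd.DataFrame) -> pd.DataFrame:
    """Per-phase mean of RMS and MPF over repetitions (missing rows skipped)."""
    return (features.groupby("phase", sort=False)[["rms", "mpf"]]
            .mean().reset_index())


def hold_series(rec: ChannelRecording,
                held: SquatPhaseSegment,
                band: tuple[float, float] | None = None) -> pd.DataFrame:
    """Per-1-s-window RMS and MPF over the wall-squat hold.

    The held interval is split into floor(duration) non-overlapping 1-s
    windows; a trailing partial second is discarded.  ``normalized_time`` is
    the window midpoint as a percentage of the hold duration, so holds of
    different lengths can be averaged on a common axis.
    """
    band = _band_for(rec, band)
    seg = held if held.rate == rec.rate else held.at_rate(rec.rate)
    start, stop = seg.start, min(seg.stop, rec.n)
    duration_s = (stop - start) / rec.rate
    if duration_s < 2.0:
        raise ValueError("held period must last at least 2 s")
    win = int(rec.rate)
    n_win = int(duration_s)
    rows = []
    for w in range(n_win):
        a = start + w * win
        x = rec.samples[a:a + win]
        t_mid = (w + 0.5) / duration_s * 100.0
        rows.append((w, t_mid, rms(x), mpf(x, rec.rate, band)))
    return pd.DataFrame(rows, columns=["window_index", "normalized_time",
                                       "rms", "mpf"])


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def group_phase_average(per_participant: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Group mean and SD of per-phase features across participants.

    Input frames are per-participant phase means (from :func:`phase_means`).
    Returns columns phase, rms_mean, rms_sd, mpf_mean, mpf_sd.
    """
    if len(per_participant) == 0:
        raise ValueError("no participants to average")
    stacked = pd.concat(per_participant, keys=range(len(per_participant)))
    out = (stacked.groupby("phase", sort=False)[["rms", "mpf"]]
           .agg(["mean", _sd]))
    out.columns = [f"{m}_{'sd' if f == '_sd' else 'mean'}" for m, f in out.columns]
    return out.reset_index()


def normalized_grid(n_points: int = 100) -> np.ndarray:
    """Common normalized-time axis (percent of hold duration)."""
    return np.linspace(0.5, 99.5, n_points)


def group_hold_average(per_participant: Sequence[pd.DataFrame],
                       n_points: int = 100) -> pd.DataFrame:
    """Average exertion series across participants on a common time grid.

    Each participant's per-window series is linearly interpolated onto a
    ``n_points``-point percentage-of-duration grid before the group mean and
    SD envelope are formed (hold lengths differ between participants).
    """
    if len(per_participant) == 0:
        raise ValueError("no participants to average")
    grid = normalized_grid(n_points)
    cols = {}
    for metric in ("rms", "mpf"):
        mat = np.vstack([
            np.interp(grid, df["normalized_time"].to_numpy(),
                      df[metric].to_numpy())
            for df in per_participant])
        cols[f"{metric}_mean"] = mat.mean(axis=0)
        cols[f"{metric}_sd"] = (np.std(mat, axis=0, ddof=1)
                                if mat.shape[0] > 1 else np.zeros(grid.size))
    return pd.DataFrame({"normalized_time": grid, **cols})
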