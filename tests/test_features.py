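"""RMS / MPF closed forms, window bookkeeping of the hold series, and
group aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myophase import (ChannelKind, ChannelRecording, SignalModelSpec,
                      SquatPhaseSegment, bandpass, generate_muscle_signal,
                      group_hold_average, group_phase_average, hold_series,
                      linear_trend, mpf, phase_features, phase_means, rms,
                      slope_for_pct_change)


@pytest.mark.parametrize("samples,expected", [
    (np.full(100, 2.5), 2.5),
    (np.full(100, -2.5), 2.5),
    (np.sin(2 * np.pi * 5 * np.arange(1000) / 1000.0), 1 / np.sqrt(2)),
    (np.array([3.0, 4.0]), np.sqrt(12.5)),
])
def test_rms_closed_forms(samples, expected):
    assert rms(samples) == pytest.approx(expected, rel=1e-9)


def test_rms_rejects_empty():
    with pytest.raises(ValueError):
        rms([])


@settings(deadline=None, max_examples=25)
@given(st.floats(min_value=-100, max_value=100))
def test_rms_positively_homogeneous(a):
    x = np.linspace(-1, 1, 64)
    assert rms(a * x) == pytest.approx(abs(a) * rms(x), abs=1e-12)


def test_mpf_single_tone_at_line_frequency():
    t = np.arange(2000) / 1000.0
    x = np.sin(2 * np.pi * 10 * t)
    assert mpf(x, 1000.0, (2, 100)) == pytest.approx(10.0, abs=0.5)


def test_mpf_equal_power_tones_average_to_midpoint():
    t = np.arange(2000) / 1000.0
    x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 20 * t)
    assert mpf(x, 1000.0, (2, 100)) == pytest.approx(15.0, abs=0.5)


def test_mpf_flat_spectrum_noise_centroid_is_midband():
    """White noise is spectrally flat, so the band-restricted centroid over
    (2, 100) Hz converges to the midband 51 Hz across realizations."""
    rng = np.random.default_rng(17)
    vals = [mpf(rng.normal(size=1000), 1000.0, (2, 100)) for _ in range(300)]
    assert np.mean(vals) == pytest.approx(51.0, abs=2.0)


def test_mpf_amplitude_invariant_and_inside_band():
    rng = np.random.default_rng(2)
    x = rng.normal(size=3000)
    band = (10.0, 200.0)
    v = mpf(x, 1000.0, band)
    assert mpf(100.0 * x, 1000.0, band) == pytest.approx(v, rel=1e-9)
    assert band[0] <= v <= band[1]


def test_mpf_rejects_zero_in_band_power_and_bad_band():
    with pytest.raises(ValueError):
        mpf(np.zeros(3000), 1000.0, (2, 50))  # no in-band power at all
    with pytest.raises(ValueError):
        mpf(np.ones(3000), 1000.0, (100, 600))  # band above Nyquist


def _rec_with_reps(rate=1000.0, n_reps=5, phase_s=1.0):
    """Identical 20 Hz bursts in every phase of every repetition."""
    n = int(phase_s * rate)
    t = np.arange(n) / rate
    burst = np.sin(2 * np.pi * 20 * t)
    segs, chunks, pos = [], [], 0
    for rep in range(n_reps):
        for phase in ("entering", "held", "exiting"):
            segs.append(SquatPhaseSegment(rep, phase, pos, pos + n, rate))
            chunks.append(burst)
            pos += n
    return ChannelRecording(np.concatenate(chunks), rate, ChannelKind.MMG), segs


def test_identical_repetitions_give_identical_features():
    rec, segs = _rec_with_reps()
    feats = phase_features(rec, segs)
    assert len(feats) == 15 and not feats.missing.any()
    for phase in ("entering", "held", "exiting"):
        vals = feats[feats.phase == phase]
        assert vals.rms.std() == pytest.approx(0.0, abs=1e-12)
        assert phase_means(feats).set_index("phase").loc[phase, "rms"] == \
            pytest.approx(vals.rms.iloc[0])


def test_short_segment_flagged_missing_and_skipped_in_means():
    rec, segs = _rec_with_reps()
    # replace one held segment by a 100 ms sliver
    idx = next(i for i, s in enumerate(segs) if s.phase == "held")
    s = segs[idx]
    segs[idx] = SquatPhaseSegment(s.rep_index, "held", s.start, s.start + 100, s.rate)
    feats = phase_features(rec, segs)
    held = feats[feats.phase == "held"]
    assert held.missing.sum() == 1
    assert np.isnan(held[held.missing].rms).all()
    mean = phase_means(feats).set_index("phase").loc["held", "rms"]
    assert mean == pytest.approx(held[~held.missing].rms.mean())


def test_hold_series_window_count_floors_duration():
    rate = 1000.0
    n = int(88.5 * rate)
    rng = np.random.default_rng(3)
    rec = ChannelRecording(rng.normal(size=n), rate, ChannelKind.MMG)
    held = SquatPhaseSegment(0, "held", 0, n, rate)
    series = hold_series(rec, held, band=(2, 100))
    assert len(series) == 88
    assert series.normalized_time.between(0, 100).all()
    assert series.normalized_time.is_monotonic_increasing


def test_hold_series_rejects_short_hold():
    rec = ChannelRecording(np.random.default_rng(0).normal(size=1500),
                           1000.0, ChannelKind.MMG)
    with pytest.raises(ValueError):
        hold_series(rec, SquatPhaseSegment(0, "held", 0, 1500, 1000.0),
                    band=(2, 100))


def test_stationary_hold_has_near_zero_rms_slope(hold_trace, mmg_rest_model):
    _, _, _, truth = hold_trace
    rec = generate_muscle_signal(mmg_rest_model, truth, "MMG", seed=55)
    series = hold_series(bandpass(rec), truth.segments_of("held")[0])
    tr = linear_trend(series.normalized_time, series.rms)
    # slope per % of hold; full-range drift below 3% of the mean level
    assert abs(tr.slope * 100) < 0.03 * series.rms.mean()


def test_windowed_mpf_monotone_under_centre_sweep(hold_trace):
    _, _, _, truth = hold_trace
    model = SignalModelSpec.emg_default(
        fatigue_rms_slope=0.0, fatigue_mpf_slope=slope_for_pct_change(-18.0))
    rec = generate_muscle_signal(model, truth, "EMG", seed=56)
    series = hold_series(bandpass(rec), truth.segments_of("held")[0])
    halves = np.array_split(series.mpf.to_numpy(), 4)
    quarter_means = [h.mean() for h in halves]
    assert all(a > b for a, b in zip(quarter_means, quarter_means[1:]))


def test_group_phase_average_single_participant_sd_zero():
    df = pd.DataFrame({"phase": ["entering", "held", "exiting"],
                       "rms": [1.0, 2.0, 3.0], "mpf": [5.0, 6.0, 7.0]})
    out = group_phase_average([df]).set_index("phase")
    assert out.loc["held", "rms_mean"] == 2.0
    assert (out[["rms_sd", "mpf_sd"]] == 0.0).all().all()


def test_group_hold_average_symmetry_and_envelope():
    t = np.linspace(0.5, 99.5, 50)
    a = pd.DataFrame({"normalized_time": t, "rms": 1 + t / 100, "mpf": 50 - t / 10})
    b = pd.DataFrame({"normalized_time": t, "rms": 1 - t / 100, "mpf": 50 + t / 10})
    out = group_hold_average([a, b], n_points=100)
    np.testing.assert_allclose(out.rms_mean, 1.0, atol=1e-9)
    np.testing.assert_allclose(out.mpf_mean, 50.0, atol=1e-9)
    assert (out.rms_sd > 0).all()
    single = group_hold_average([a], n_points=100)
    assert (single.rms_sd == 0).all()


def test_group_average_rejects_empty_input():
    with pytest.raises(ValueError):
        group_hold_average([])
    with pytest.raises(ValueError):
        group_phase_average([])
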