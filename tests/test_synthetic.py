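"""Generator contracts: protocol structure, determinism, spectral shaping,
envelope fidelity and the endurance-time distribution."""

import numpy as np
import pytest
from scipy import signal as ss

from myophase import (ChannelKind, ProtocolSpec, SignalModelSpec,
                      bandpass, draw_hold_durations, estimate_flexion,
                      generate_accel_trace, generate_muscle_signal,
                      generate_session, hold_series, isolate_hold, mpf,
                      pct_change_for_slope, rms, slope_for_pct_change,
                      smooth_accel)
from myophase.synthetic import _shaping_sos


def test_five_rep_protocol_yields_five_phase_triples(pre_trace):
    _, _, _, truth = pre_trace
    for phase in ("entering", "held", "exiting"):
        assert len(truth.segments_of(phase)) == 5
    assert truth.n_reps == 5


def test_truth_segments_partition_without_overlap(pre_trace, hold_trace):
    for bundle in (pre_trace, hold_trace):
        truth = bundle[3]
        segs = truth.phase_segments
        assert all(a.stop <= b.start for a, b in zip(segs, segs[1:]))
        assert segs[-1].stop <= truth.n_samples
        # within each repetition the three phases are contiguous
        for rep in range(truth.n_reps):
            e, h, x = [s for s in segs if s.rep_index == rep]
            assert (e.phase, h.phase, x.phase) == ("entering", "held", "exiting")
            assert e.stop == h.start and h.stop == x.start


def test_noise_free_plateau_rotated_by_configured_flexion():
    proto = ProtocolSpec(pre_flexion_deg=75.0)
    ax, ay, az, truth = generate_accel_trace(proto, seed=0, noise_std=0.0)
    held = truth.segments_of("held")[0]
    est = estimate_flexion((ax, ay, az), truth.baseline, (held.start, held.stop))
    assert est.angle_deg == pytest.approx(75.0, abs=1e-6)


def test_same_seed_reproduces_traces_exactly(protocol):
    a = generate_accel_trace(protocol, seed=42)
    b = generate_accel_trace(protocol, seed=42)
    for ra, rb in zip(a[:3], b[:3]):
        np.testing.assert_array_equal(ra.samples, rb.samples)
    truth = a[3]
    ma = generate_muscle_signal(SignalModelSpec.mmg_default(), truth, "MMG", seed=9)
    mb = generate_muscle_signal(SignalModelSpec.mmg_default(), truth, "MMG", seed=9)
    np.testing.assert_array_equal(ma.samples, mb.samples)


def test_invalid_protocol_and_rate_rejected(protocol):
    with pytest.raises(ValueError):
        ProtocolSpec(squat_hold_s=0.0)
    with pytest.raises(ValueError):
        ProtocolSpec(wall_squat_duration_s=5.0)
    with pytest.raises(ValueError):
        generate_accel_trace(protocol, sample_rate=0.0)


def test_peak_outside_band_and_empty_truth_rejected(pre_trace):
    truth = pre_trace[3]
    with pytest.raises(ValueError):
        SignalModelSpec.mmg_default(peak_hz=150.0)
    empty = type(truth)(phase_segments=[], knee_flexion_deg=[],
                        baseline=(0, 10), n_samples=100, rate=50.0)
    with pytest.raises(ValueError):
        generate_muscle_signal(SignalModelSpec.mmg_default(), empty, "MMG")


def test_phase_rms_envelope_matches_rest_times_gain(pre_trace, mmg_rest_model,
                                                    mmg_rest_signal):
    _, _, _, truth = pre_trace
    rec = mmg_rest_signal
    for phase, gain in mmg_rest_model.phase_gain.items():
        target = mmg_rest_model.rest_rms * gain
        for seg in truth.segments_of(phase):
            s = seg.at_rate(rec.rate)
            measured = rms(rec.samples[s.start:s.stop])
            assert measured == pytest.approx(target, rel=0.03)


def test_rest_mpf_near_peak_and_analytic_centroid(pre_trace, mmg_rest_signal):
    _, _, _, truth = pre_trace
    rec = mmg_rest_signal
    a, b = truth.baseline
    x = rec.samples[int(a * 20):int(b * 20)]  # 50 Hz -> 1 kHz indices
    measured = mpf(x, rec.rate, (2.0, 100.0))
    assert 7.0 <= measured <= 8.0
    # independent oracle: centroid of the shaping cascade's analytic response
    sos1 = _shaping_sos(7.5, 2.0, rec.rate)
    sos2 = ss.butter(4, [2, 100], btype="bandpass", fs=rec.rate, output="sos")
    w = np.linspace(0.1, 150, 30000)
    h = np.abs(ss.sosfreqz(sos1, worN=w, fs=rec.rate)[1]
               * ss.sosfreqz(sos2, worN=w, fs=rec.rate)[1]) ** 2
    analytic = float((w * h).sum() / h.sum())
    assert measured == pytest.approx(analytic, abs=0.5)


@pytest.mark.parametrize("channel,band", [("MMG", (2.0, 100.0)),
                                          ("EMG", (10.0, 495.0))])
def test_psd_mass_concentrated_in_channel_band(pre_trace, channel, band):
    _, _, _, truth = pre_trace
    model = SignalModelSpec.default_for(channel)
    rec = generate_muscle_signal(model, truth, channel, seed=21)
    f, p = ss.welch(rec.samples, fs=rec.rate, nperseg=4096)
    sel = (f >= band[0]) & (f <= band[1])
    assert p[~sel].sum() / p.sum() < 0.05


def test_zero_slope_hold_has_flat_first_last_rms(hold_trace, mmg_rest_model):
    """Monte-Carlo sampling error of the equalised generator keeps the
    first-vs-last-10% RMS difference under 3% when no trend is injected."""
    _, _, _, truth = hold_trace
    held = truth.segments_of("held")[0]
    diffs = []
    for seed in range(4):
        rec = generate_muscle_signal(mmg_rest_model, truth, "MMG", seed=30 + seed)
        s = held.at_rate(rec.rate)
        n = s.stop - s.start
        first = rms(rec.samples[s.start:s.start + n // 10])
        last = rms(rec.samples[s.stop - n // 10:s.stop])
        diffs.append(abs(last - first) / first * 100.0)
    assert np.mean(diffs) < 3.0


def test_injected_rms_trend_recovered_by_feature_pipeline(hold_trace):
    _, _, _, truth = hold_trace
    model = SignalModelSpec.mmg_default(
        fatigue_rms_slope=slope_for_pct_change(30.0), fatigue_mpf_slope=0.0)
    rec = generate_muscle_signal(model, truth, "MMG", seed=40)
    held = truth.segments_of("held")[0]
    series = hold_series(bandpass(rec), held)
    # spec of the ramp: last/first window ratio ~ 1 + slope
    ratio = (series.rms.iloc[-3:].mean() / series.rms.iloc[:3].mean())
    assert ratio == pytest.approx(1.0 + model.fatigue_rms_slope, abs=0.05)
    n10 = max(len(series) // 10, 1)
    pct = (series.rms.iloc[-n10:].mean() / series.rms.iloc[:n10].mean() - 1) * 100
    assert pct == pytest.approx(30.0, abs=5.0)


def test_slope_pct_change_maps_are_inverse():
    for pct in (-18.07, -5.98, 15.2, 29.35, 30.0):
        assert pct_change_for_slope(slope_for_pct_change(pct)) == pytest.approx(pct)


def test_hold_duration_distribution_mean():
    rng = np.random.default_rng(123)
    draws = draw_hold_durations(10_000, rng)
    assert abs(draws.mean() - 88.5) < 2.0
    assert draws.min() >= 20.0


def test_session_bundle_structure_and_determinism(tmp_path):
    from myophase import write_session
    proto = ProtocolSpec(wall_squat_duration_s=30.0)
    b1 = generate_session(proto, n_participants=3, seed=77, stages=("pre",))
    b2 = generate_session(proto, n_participants=3, seed=77, stages=("pre",))
    assert len(b1["participants"]) == 3
    sigs = [p["stages"]["pre"]["MMG"].samples for p in b1["participants"]]
    # distinct participants, identical regeneration
    assert not np.allclose(sigs[0], sigs[1])
    for pa, pb in zip(b1["participants"], b2["participants"]):
        np.testing.assert_array_equal(pa["stages"]["pre"]["MMG"].samples,
                                      pb["stages"]["pre"]["MMG"].samples)
    m1 = write_session(b1, tmp_path / "a")
    m2 = write_session(b2, tmp_path / "b")
    f1 = sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*.csv"))
    for rel in f1:
        assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()


def test_hold_stage_records_injected_trends():
    proto = ProtocolSpec(wall_squat_duration_s=30.0)
    b = generate_session(proto, n_participants=1, seed=5, stages=("hold",))
    truth = b["participants"][0]["stages"]["hold"]["truth"]
    assert truth.injected_rms_change_pct["MMG"] == pytest.approx(29.35)
    assert truth.injected_mpf_change_pct["EMG"] == pytest.approx(-18.07)
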