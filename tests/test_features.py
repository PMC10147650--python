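"""Spectral, event, velocity and propagation feature extraction on
constructed signals with known answers."""

import numpy as np
import pytest

from gutwave import (
    ExtractorConfig,
    MEARecording,
    detect_events,
    dominant_frequency_power,
    estimate_velocity,
    extract_features,
    propagation_features,
    quality_check,
    rhythm_percentages,
    validate_ef_vector,
    waveform_features,
    welch_spectrum,
)
from gutwave.errors import (
    DegenerateGeometryError,
    InsufficientEventsError,
    NoRhythmError,
    RejectedRecordingError,
)
from gutwave.recording import PROP_PCT_FEATURES, RHYTHM_PCT_FEATURES
from gutwave.synth import StudyDesign, make_drug_library, simulate_recording
from conftest import make_pulse_recording

FS = 10.0


def sine(freq_hz, duration=300.0, fs=FS, amp=100.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t + phase)


# ---------------------------------------------------------------------------
# Welch spectrum and spectral features
# ---------------------------------------------------------------------------


def test_welch_recovers_sine_frequency(cfg):
    freqs, psd = welch_spectrum(sine(0.2), FS, config=cfg)
    df = freqs[1] - freqs[0]
    assert abs(freqs[np.argmax(psd)] - 0.2) <= df


def test_welch_dc_signal_has_no_power(cfg):
    freqs, psd = welch_spectrum(np.full(3000, 42.0), FS, config=cfg)
    assert psd.sum() < 1e-12


def test_welch_peak_power_ratio_follows_amplitude_square(cfg):
    x = sine(0.1, amp=2.0) + sine(0.3, amp=1.0)
    freqs, psd = welch_spectrum(x, FS, config=cfg)
    p1 = psd[np.argmin(np.abs(freqs - 0.1))]
    p2 = psd[np.argmin(np.abs(freqs - 0.3))]
    assert p1 / p2 == pytest.approx(4.0, rel=0.1)


def test_dominant_frequency_of_12cpm_sine(cfg):
    freqs, psd = welch_spectrum(sine(0.2), FS, config=cfg)
    dom, power = dominant_frequency_power(freqs, psd, cfg)
    assert dom == pytest.approx(12.0, abs=(freqs[1] - freqs[0]) * 60)
    assert power > 0


def test_dominant_frequency_tie_breaks_toward_lower(cfg):
    freqs = np.linspace(0.0, 1.0, 201)
    psd = np.zeros_like(freqs)
    i6 = np.argmin(np.abs(freqs - 0.1))
    i18 = np.argmin(np.abs(freqs - 0.3))
    psd[i6] = psd[i18] = 5.0
    dom, _ = dominant_frequency_power(freqs, psd, cfg)
    assert dom == pytest.approx(6.0, abs=0.5)


def test_dominant_frequency_empty_band_errors(cfg):
    freqs = np.linspace(0, 1, 100)
    with pytest.raises(NoRhythmError):
        dominant_frequency_power(freqs, np.zeros(100), cfg)


def test_rhythm_percentages_partition(cfg):
    # Ileum base 12 cpm: an in-band sine puts nearly all power in 'normal'.
    freqs, psd = welch_spectrum(sine(0.2), FS, config=cfg)
    b, n, t = rhythm_percentages(freqs, psd, "ileum", cfg)
    assert n > 95
    assert b + n + t == pytest.approx(100.0, abs=1e-9)

    freqs, psd = welch_spectrum(sine(0.2 * 0.4), FS, config=cfg)
    b, n, t = rhythm_percentages(freqs, psd, "ileum", cfg)
    assert b > 95

    x = sine(0.2 * 0.4) + sine(0.2 * 2.0)
    freqs, psd = welch_spectrum(x, FS, config=cfg)
    b, n, t = rhythm_percentages(freqs, psd, "ileum", cfg)
    assert b == pytest.approx(t, abs=5.0)


def test_rhythm_percentages_zero_power_errors(cfg):
    freqs = np.linspace(0, 1, 100)
    with pytest.raises(NoRhythmError):
        rhythm_percentages(freqs, np.zeros(100), "colon", cfg)


# ---------------------------------------------------------------------------
# Events and waveform features
# ---------------------------------------------------------------------------


def test_event_count_on_noiseless_wave(cfg):
    ev = detect_events(sine(0.2), FS, cfg)
    assert abs(len(ev) - 60) <= 1


def test_flat_signal_yields_no_events(cfg):
    assert len(detect_events(np.zeros(3000), FS, cfg)) == 0


def test_refractory_rule_suppresses_doubled_peak(cfg):
    x = sine(0.2)
    t = np.arange(len(x)) / FS
    # Extra bump 1 s after a genuine peak, well inside the refractory window.
    x = x + 60.0 * np.exp(-0.5 * ((t - 31.25 - 1.0) / 0.2) ** 2)
    ev = detect_events(x, FS, cfg)
    assert abs(len(ev) - 60) <= 1


def test_waveform_reciprocity_and_linearity(cfg):
    ev = detect_events(sine(0.2), FS, cfg)
    avg_f, amp, period, slope = waveform_features(ev)
    assert avg_f == pytest.approx(12.0, rel=0.02)
    assert period == pytest.approx(5.0, rel=0.02)

    ev2 = detect_events(2.0 * sine(0.2), FS, cfg)
    _, amp2, _, slope2 = waveform_features(ev2)
    assert amp2 / amp == pytest.approx(2.0, rel=0.02)
    assert slope2 / slope == pytest.approx(2.0, rel=0.05)


def test_sawtooth_slope_exceeds_sine_slope(cfg):
    from scipy.signal import sawtooth

    t = np.arange(3000) / FS
    # width=0.1: fast upstroke over 10% of the cycle.
    saw = 100.0 * sawtooth(2 * np.pi * 0.05 * t, width=0.1)
    sin = 100.0 * np.sin(2 * np.pi * 0.05 * t)
    s_saw = waveform_features(detect_events(saw, FS, cfg))[3]
    s_sin = waveform_features(detect_events(sin, FS, cfg))[3]
    assert s_saw > s_sin


def test_waveform_requires_two_events(cfg):
    ev = detect_events(np.zeros(3000), FS, cfg)
    with pytest.raises(InsufficientEventsError):
        waveform_features(ev)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def test_quality_rejects_flatline(cfg):
    rec = MEARecording(np.zeros((16, 1200)), 4.0, 4, 4, 300.0, "ileum")
    verdict = quality_check(rec, cfg)
    assert not verdict.passed and "flatline" in verdict.reasons


def test_quality_passes_clean_wave(plane_wave, cfg):
    assert quality_check(plane_wave, cfg).passed


def test_quality_rejects_white_noise(cfg):
    rng = np.random.default_rng(5)
    rec = MEARecording(rng.normal(0, 30, (16, 1200)), 4.0, 4, 4, 300.0, "ileum")
    verdict = quality_check(rec, cfg)
    assert not verdict.passed and "no_detectable_rhythm" in verdict.reasons


def test_extract_raises_on_rejected_recording(cfg):
    rec = MEARecording(np.zeros((16, 1200)), 4.0, 4, 4, 300.0, "ileum")
    with pytest.raises(RejectedRecordingError):
        extract_features(rec, cfg)


# ---------------------------------------------------------------------------
# Velocity
# ---------------------------------------------------------------------------


def test_velocity_recovered_within_five_percent(plane_wave, cfg):
    est = estimate_velocity(plane_wave, cfg)
    assert est.speed_um_s == pytest.approx(600.0, rel=0.05)


def test_velocity_direction_invariant(plane_wave, cfg):
    reversed_wave = MEARecording(
        plane_wave.signals.reshape(8, 8, -1)[:, ::-1].reshape(64, -1),
        plane_wave.fs, 8, 8, plane_wave.pitch_um, plane_wave.tissue,
    )
    est = estimate_velocity(reversed_wave, cfg)
    assert est.speed_um_s == pytest.approx(600.0, rel=0.05)


def test_velocity_capped_for_synchronous_activity(plane_wave, cfg):
    sync = MEARecording(
        np.tile(plane_wave.signals[:1], (64, 1)),
        plane_wave.fs, 8, 8, plane_wave.pitch_um, plane_wave.tissue,
    )
    est = estimate_velocity(sync, cfg)
    assert est.capped and est.speed_um_s == cfg.velocity_max_um_s


def test_velocity_requires_2d_grid(plane_wave, cfg):
    line = MEARecording(
        plane_wave.signals[:8], plane_wave.fs, 1, 8,
        plane_wave.pitch_um, plane_wave.tissue,
    )
    with pytest.raises(DegenerateGeometryError):
        estimate_velocity(line, cfg)


# ---------------------------------------------------------------------------
# Propagation patterns
# ---------------------------------------------------------------------------


def test_plane_wave_classified_forward(plane_wave, cfg):
    pct, change = propagation_features(plane_wave, cfg)
    assert pct["forward"] == 100.0
    assert change == 0.0


def test_alternating_waves_split_forward_backward(cfg):
    rows = cols = 6
    fs, pitch, period, lag = 4.0, 300.0, 8.0, 0.4
    times = [[] for _ in range(rows * cols)]
    for k in range(14):
        t0 = 10.0 + k * period
        for ch in range(rows * cols):
            col = ch % cols
            offset = col * lag if k % 2 == 0 else (cols - 1 - col) * lag
            times[ch].append(t0 + offset)
    rec = make_pulse_recording(times, fs, rows, cols, pitch)
    pct, change = propagation_features(rec, ExtractorConfig())
    assert pct["forward"] == pytest.approx(50.0, abs=100.0 / 14 + 1e-9)
    assert pct["backward"] == pytest.approx(50.0, abs=100.0 / 14 + 1e-9)
    assert change == pytest.approx(0.5, abs=0.05)


def test_noise_dominated_by_unorganized(cfg):
    rng = np.random.default_rng(11)
    rows = cols = 6
    times = [np.sort(rng.uniform(5, 115, size=14)).tolist() for _ in range(rows * cols)]
    rec = make_pulse_recording(times, 4.0, rows, cols, 300.0)
    lenient = ExtractorConfig(peak_median_ratio=0.0, min_amplitude_uv=0.0)
    pct, _ = propagation_features(rec, lenient)
    assert pct["unorganized"] > 60.0


def test_propagation_requires_rhythm(cfg):
    rec = MEARecording(np.zeros((16, 1200)), 4.0, 4, 4, 300.0, "ileum")
    with pytest.raises(NoRhythmError):
        propagation_features(rec, cfg)


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------


def test_extraction_on_noiseless_wave(plane_wave, cfg):
    ef = extract_features(plane_wave, cfg)
    validate_ef_vector(ef)
    assert ef["dominant_frequency"] == pytest.approx(12.0, rel=0.05)
    assert ef["average_frequency"] == pytest.approx(12.0, rel=0.05)
    assert ef["pct_normal"] > 95
    assert ef["pct_prop_forward"] == 100.0


def test_extraction_deterministic(plane_wave, cfg):
    assert extract_features(plane_wave, cfg).equals(extract_features(plane_wave, cfg))


def test_ef_invariants_over_random_recordings(fast_design, cfg):
    lib = make_drug_library(4, 2, seed=9)
    rng = np.random.default_rng(1)
    for i in range(24):
        tissue = ["stomach", "duodenum", "ileum", "colon"][i % 4]
        profile = lib[i % 4]
        phase = "post_drug" if i % 2 else "baseline"
        rec = simulate_recording(
            profile if phase == "post_drug" else None,
            tissue, fast_design.doses[i % 3], phase, fast_design,
            seed=int(rng.integers(2**31)),
        )
        ef = extract_features(rec, cfg)
        validate_ef_vector(ef)
        assert sum(ef[f] for f in RHYTHM_PCT_FEATURES) == pytest.approx(100, abs=1e-6)
        assert sum(ef[f] for f in PROP_PCT_FEATURES) == pytest.approx(100, abs=1e-6)


def test_voltage_scale_invariance(fast_design, cfg):
    rec = simulate_recording(None, "colon", 1e-5, "baseline", fast_design, seed=21)
    scaled = MEARecording(
        3.0 * rec.signals, rec.fs, rec.grid_rows, rec.grid_cols,
        rec.pitch_um, rec.tissue,
    )
    ef = extract_features(rec, cfg)
    ef3 = extract_features(scaled, cfg)
    assert ef3["amplitude"] == pytest.approx(3.0 * ef["amplitude"], rel=1e-9)
    assert ef3["slope"] == pytest.approx(3.0 * ef["slope"], rel=1e-9)
    assert ef3["dominant_power"] == pytest.approx(9.0 * ef["dominant_power"], rel=1e-9)
    for name in (
        "dominant_frequency", "average_frequency", "period", "velocity",
        "pct_brady", "pct_normal", "pct_tachy",
        "mse_scale_1", "mse_scale_5",
        "dfa_alpha_short", "dfa_alpha_long", "dfa_alpha_overall",
        "pct_prop_forward", "prop_pattern_change_index",
    ):
        assert ef3[name] == pytest.approx(ef[name], rel=1e-9, abs=1e-9)
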