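import numpy as np
import pytest

from gutwave import ExtractorConfig, StudyDesign
from gutwave.synth import simulate_recording


@pytest.fixture
def cfg():
    return ExtractorConfig()


@pytest.fixture
def fast_design():
    """Desk-scale acquisition settings for unit tests (keeps DFA's 4x64
    sample requirement satisfied at 4 Hz)."""
    return StudyDesign(n_drugs=2, duration_s=120.0, fs=4.0)


@pytest.fixture
def noiseless_design():
    # Pure fundamental (no harmonic) so spectral power sits in one band.
    return StudyDesign(
        n_drugs=2, duration_s=120.0, fs=4.0, noise_uv=0.0, base_jitter=0.0,
        harmonic=0.0,
    )


@pytest.fixture
def plane_wave(noiseless_design):
    """Noiseless 12 cpm plane wave on the 8x8 grid at 600 um/s."""
    return simulate_recording(
        None, "ileum", 1e-5, "baseline", noiseless_design, seed=7
    )


def make_pulse_recording(wave_times_per_channel, fs, rows, cols, pitch, tissue="ileum"):
    """Recording whose channels carry narrow Gaussian pulses at prescribed
    times; used to construct specific propagation patterns."""
    duration = max(max(t) for t in wave_times_per_channel) + 5.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    signals = np.zeros((rows * cols, n))
    for ch, times in enumerate(wave_times_per_channel):
        for tc in times:
            signals[ch] += 100.0 * np.exp(-0.5 * ((t - tc) / 0.8) ** 2)
    from gutwave import MEARecording

    return MEARecording(
        signals=signals,
        fs=fs,
        grid_rows=rows,
        grid_cols=cols,
        pitch_um=pitch,
        tissue=tissue,
    )
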