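import numpy as np
import pytest

from fecg.signal_model import RPeakSeries, Trace
from fecg.synthgen import BeatShape, HeartConfig, NoiseConfig, SynthConfig, gen_beat_train


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_periodic_ecg(
    n_beats: int = 20,
    rr_s: float = 0.75,
    fs: float = 500.0,
    shape: BeatShape | None = None,
    amplitude_uv: float = 100.0,
) -> tuple[Trace, RPeakSeries]:
    """Strictly periodic ECG with identical beats (hr_sd = 0)."""
    hr = 60.0 / rr_s
    duration = (n_beats + 2) * rr_s
    trace, peaks = gen_beat_train(
        hr, 0.0, shape or BeatShape.maternal(), duration, fs, seed=0
    )
    return trace.with_samples(trace.samples * amplitude_uv), peaks


@pytest.fixture
def periodic_ecg():
    return make_periodic_ecg()


@pytest.fixture
def fast_synth_config():
    """Small but realistic mixture config for pipeline tests."""
    return SynthConfig(
        duration_s=20.0,
        fs=500.0,
        maternal=HeartConfig(80.0, 3.0, 500.0, BeatShape.maternal()),
        fetal=HeartConfig(140.0, 5.0, 20.0, BeatShape.fetal()),
        fetal_amplitude_direct_uv=150.0,
        noise=NoiseConfig(baseline_uv=30.0, powerline_uv=15.0,
                          broadband_uv=8.0, emg_uv=8.0),
        direct_noise=NoiseConfig(baseline_uv=20.0, powerline_uv=8.0,
                                 broadband_uv=6.0, emg_uv=6.0),
        n_abdominal_channels=2,
        seed=7,
    )
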