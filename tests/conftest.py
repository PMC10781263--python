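import numpy as np
import pytest

from ppgbench import PhysioParams, Signal, generate_clean

FS = 1000.0


@pytest.fixture(scope="session")
def clean_60bpm():
    """120 s of metronomic 60 BPM pulses with no noise or baseline wander."""
    params = PhysioParams(mean_hr_bpm=60.0, sdnn_s=0.0, noise_sd=0.0,
                          resp_amp=0.0, duration_s=120.0, seed=1)
    sig, truth = generate_clean(params, FS)
    return params, sig, truth


@pytest.fixture(scope="session")
def clean_70bpm():
    """120 s of realistic clean physiology (default jitter and noise)."""
    params = PhysioParams(mean_hr_bpm=70.0, duration_s=120.0, seed=11)
    sig, truth = generate_clean(params, FS)
    return params, sig, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_signal(samples, fs=FS, **kw) -> Signal:
    return Signal(samples=np.asarray(samples, float), fs=fs, **kw)
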