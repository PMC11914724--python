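import numpy as np
import pytest

import ecgrisk as er


@pytest.fixture(scope="session")
def base_signal() -> er.ECGSignal:
    """A typical 10-s, 500 Hz 12-lead record used across tests."""
    return er.generate_signal(er.WaveTemplate(), heart_rate=72.0, fs=500.0,
                              duration=10.0, noise_sd=0.01, seed=5)


@pytest.fixture(scope="session")
def page(base_signal) -> er.RenderedECG:
    """Default hospital-style colour page with grid and rhythm strips."""
    return er.render_paper_ecg(base_signal)


@pytest.fixture(scope="session")
def digitized(page) -> er.DigitizedECG:
    return er.digitize_ecg(page)


@pytest.fixture(scope="session")
def reference(base_signal) -> er.ECGSignal:
    """The source signal after the shared filter/resample chain."""
    return er.filter_resample(base_signal)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
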