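import numpy as np
import pytest

from ripplesim import (
    AsynchronousParams,
    LFPSignal,
    generate_asynchronous,
    make_ap_template,
    make_psp_template,
)


@pytest.fixture(scope="session")
def ap_template():
    return make_ap_template()


@pytest.fixture(scope="session")
def psp_template():
    return make_psp_template()


@pytest.fixture(scope="session")
def small_async_events():
    """A few short asynchronous trains for oracle-equivalence checks."""
    params = AsynchronousParams(
        mu_pop=5.0, sigma_mu=0.2, sigma_jitter=0.3, n_cells=5, duration=200.0
    )
    return generate_asynchronous(params, seed=7)


def make_tone(freq_hz: float, duration_ms: float = 1000.0, fs: float = 10_000.0,
              amplitude: float = 1.0) -> LFPSignal:
    t = np.arange(int(duration_ms * fs / 1000.0)) / fs
    return LFPSignal(amplitude * np.sin(2 * np.pi * freq_hz * t), fs)


@pytest.fixture(scope="session")
def tone_200hz():
    return make_tone(200.0)
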