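import numpy as np
import pytest

from headseg import SessionDesign, generate_session


@pytest.fixture(scope="session")
def quick_design():
    """A one-block, six-movement design: fast to generate, same trial anatomy."""
    return SessionDesign(n_blocks=1, movements_per_session=6)


@pytest.fixture(scope="session")
def quick_session(quick_design):
    return generate_session(quick_design, noise_sd=0.5, drift_amp=2.0,
                            participant_id="p01", seed=5)


@pytest.fixture(scope="session")
def noiseless_session(quick_design):
    return generate_session(quick_design, noise_sd=0.0, drift_amp=0.0,
                            participant_id="p01", seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
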