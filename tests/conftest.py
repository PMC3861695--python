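import numpy as np
import pytest

import nirstate as ns


@pytest.fixture(scope="session")
def design():
    """The study's default block design (400 s, 2500 samples at 6.25 Hz)."""
    return ns.build_block_design()


@pytest.fixture(scope="session")
def small_design():
    """A short design for classifier-heavy tests (112 s, 700 samples)."""
    return ns.build_block_design(n_alternations=3)


@pytest.fixture(scope="session")
def layout():
    return ns.default_probe_layout()


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free, physiology-free simulation parameters."""
    return ns.SimulationParams(
        noise_sd=0.0,
        shared_noise_sd=0.0,
        channel_drift_step_sd=0.0,
        coupling=0.0,
        physiology=ns.PhysiologyParams(components=(), drift_step_sd=0.0),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
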