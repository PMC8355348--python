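import numpy as np
import pytest

from thetaburst import SynthConfig, simulate_session


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def control_session():
    """Control-preset session reused across modules: 600 s, 10 cells."""
    cfg = SynthConfig(duration=600.0, n_cells=10, seed=101)
    session, truths = simulate_session(cfg)
    return cfg, session, truths


@pytest.fixture(scope="session")
def mutant_session():
    cfg = SynthConfig(duration=600.0, n_cells=10, seed=202, preset="mutant")
    session, truths = simulate_session(cfg)
    return cfg, session, truths
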