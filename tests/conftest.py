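import numpy as np
import pytest

from hypercoh import coherence, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_grid():
    return coherence.band_grid()


@pytest.fixture(scope="session")
def coupled_dyad():
    """One simulated dyad with a 0.09 Hz coupling always on (3 channels,
    300 s), reused by coherence and pipeline tests."""
    params = simulate.SimParams(
        n_channels=3,
        duration=300.0,
        coupling_pairs=(simulate.CouplingPair(1, 2, 0.09, 2.0),),
        event_spec=simulate.EventSpec(lock_mode="always"),
        seed=42,
    )
    hb_a, hb_b, truth = simulate.simulate_dyad(params)
    return params, hb_a, hb_b, truth
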