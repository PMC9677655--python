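import numpy as np
import pytest

from patsep import (
    InputGenConfig,
    ResponderConfig,
    generate_input_set,
    simulate_granule_cell,
)


@pytest.fixture(scope="session")
def default_input_set():
    """One accepted input-train set at protocol defaults (fixed seed)."""
    return generate_input_set(InputGenConfig(seed=123))


@pytest.fixture(scope="session")
def identity_recording(default_input_set):
    """Recording whose output sweeps are exact copies of the inputs."""
    return simulate_granule_cell(
        default_input_set.trains, ResponderConfig.identity(), cell_id="ident"
    )


@pytest.fixture(scope="session")
def stochastic_recording(default_input_set):
    """Recording from the default stochastic responder (fixed seed)."""
    return simulate_granule_cell(
        default_input_set.trains, ResponderConfig(seed=77), cell_id="stoch"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
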