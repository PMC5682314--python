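import numpy as np
import pytest

from mmgtap import (
    BurstModel,
    PipelineConfig,
    SimProtocol,
    bandpass_filter,
    simulate_recording,
)

# One shared cache of simulated (recording, truth, filtered) triples so the
# detection tests and acceptance tests do not re-simulate the same seeds.
_SIM_CACHE: dict = {}


def simulated(seed: int, snr_db: float = 20.0):
    key = (seed, snr_db)
    if key not in _SIM_CACHE:
        rec, truth = simulate_recording(
            SimProtocol(), BurstModel(snr_db=snr_db), seed=seed
        )
        _SIM_CACHE[key] = (rec, truth, bandpass_filter(rec))
    return _SIM_CACHE[key]


@pytest.fixture(scope="session")
def sim_default():
    """Default-protocol recording, truth table and filtered recording."""
    return simulated(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def default_config():
    return PipelineConfig(seed=1)
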