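import pytest
from hypothesis import settings

import altqtl as aq

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return aq.SimulationConfig()


@pytest.fixture(scope="session")
def gmap(cfg):
    return aq.simulate_map(cfg)


@pytest.fixture(scope="session")
def dataset(cfg):
    return aq.simulate_dataset(cfg, seed=11)
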