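import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("suite")

from mutselpop.mutation import NucleotideMutationModel
from mutselpop.synthetic import make_scenario_bundle


@pytest.fixture(scope="session")
def hky():
    return NucleotideMutationModel.hky(2.0, (0.3, 0.2, 0.2, 0.3))


@pytest.fixture(scope="session")
def uniform_mu():
    return NucleotideMutationModel.uniform()


@pytest.fixture(scope="session")
def small_bundle():
    """Stable-landscape bundle shared across read-only tests."""
    return make_scenario_bundle({"n_sites": 1500}, seed=3)


@pytest.fixture(scope="session")
def shifted_bundle():
    return make_scenario_bundle({"n_sites": 1500, "shift_fraction": 0.3}, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
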