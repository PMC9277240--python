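import numpy as np
import pytest

from cmesyn.fixtures import (AUTOREG_TRUTH_NEG, fixture_network,
                             fixture_prior_bounds, generate_fixture)
from cmesyn.networks import (build_autoreg, build_bursty_birth_death,
                             build_immigration_death, default_init)


@pytest.fixture(scope="session")
def imm_death():
    return build_immigration_death()


@pytest.fixture(scope="session")
def autoreg_net():
    return build_autoreg(AUTOREG_TRUTH_NEG)


@pytest.fixture(scope="session")
def autoreg_truth():
    return dict(AUTOREG_TRUTH_NEG)


@pytest.fixture(scope="session")
def negfb_data():
    """The 25-cell negative-feedback time-series fixture (seed 42)."""
    data, manifest = generate_fixture("autoreg_negfb", 42)
    return data


@pytest.fixture(scope="session")
def negfb_prior():
    from cmesyn.inference import PriorBox
    return PriorBox.from_dict(fixture_prior_bounds("autoreg_negfb"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
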