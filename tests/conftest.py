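import numpy as np
import pytest

import anchormaic as am


@pytest.fixture(scope="session")
def paired_scenarios():
    """XINDI-like IPD scenario and Study-1-like comparator scenario."""
    return am.make_paired_scenarios(covariate_shift=am.STUDY1_SHIFT, seed=0)


@pytest.fixture(scope="session")
def ipd(paired_scenarios):
    return am.simulate_trial(paired_scenarios[0])


@pytest.fixture(scope="session")
def comparator_ipd(paired_scenarios):
    return am.simulate_trial(paired_scenarios[1])


@pytest.fixture(scope="session")
def agd(comparator_ipd):
    return am.aggregate_trial(comparator_ipd)


@pytest.fixture(scope="session")
def fitted(ipd, agd):
    return am.AnchoredMAIC(ipd, agd).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
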