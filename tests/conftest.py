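import warnings

import numpy as np
import pytest

from cbcflux.network import canonical_network, make_variant
from cbcflux.synthetic import scenario, generate_dataset

warnings.filterwarnings("ignore", message="Polyfit")

PAPER_TIMES = np.array([0, 0.5, 1, 2, 2.5, 3, 5, 7, 10, 15, 30, 60, 90, 120], float)


@pytest.fixture(scope="session")
def paper_times():
    return PAPER_TIMES.copy()


@pytest.fixture(scope="session")
def base_net():
    return canonical_network()


@pytest.fixture(scope="session")
def v5_net(base_net):
    return make_variant(base_net, "V5")


@pytest.fixture(scope="session")
def final_v5_clean():
    """Noise-free final-model dataset with ground truth."""
    sc = scenario("final_v5", noise_sd=0.0)
    noisy, clean, truth = generate_dataset(sc, seed=1)
    return sc, clean, truth


@pytest.fixture(scope="session")
def final_v5_noisy():
    sc = scenario("final_v5")
    noisy, clean, truth = generate_dataset(sc, seed=11)
    return sc, noisy, truth


@pytest.fixture(scope="session")
def v1_clean():
    sc = scenario("glucose_reentry", noise_sd=0.0)
    noisy, clean, truth = generate_dataset(sc, seed=2)
    return sc, clean, truth
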