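import numpy as np
import pandas as pd
import pytest

import hairpinscreen as hs


@pytest.fixture(scope="session")
def small_library():
    return hs.synthetic_library(n_pools=2, hairpins_per_pool=12, seed=7)


@pytest.fixture(scope="session")
def small_samples(small_library):
    pools = sorted({h.pool_id for h in small_library})
    return hs.synthetic_samples(pools, replicates=2, seed=7)


@pytest.fixture(scope="session")
def small_screen(small_library, small_samples):
    """A modest simulated screen with planted hits and its ground truth."""
    cfg = hs.SimulationConfig(hit_fraction=0.2, phi=0.05, mean_libsize=5e4)
    truth = hs.simulate_truth(small_library, small_samples, cfg, seed=11)
    counts = hs.simulate_counts(truth, small_library, small_samples, seed=12)
    return truth, counts


@pytest.fixture(scope="session")
def table1():
    return hs.load_table1()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
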