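import numpy as np
import pytest

from mrsplit import MRData, SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240906)


@pytest.fixture
def toy_data(rng):
    """Small strong-signal dataset: 2 strong SNPs out of 12, h2 ~ 0.5."""
    n, p = 160, 12
    G = rng.binomial(2, 0.3, size=(n, p)).astype(float)
    alpha = np.zeros(p)
    alpha[[2, 7]] = [0.8, 0.6]
    x = G @ alpha + rng.normal(size=n)
    y = 0.5 * x + rng.normal(size=n)
    return MRData(genotypes=G, exposure=x, outcome=y)


@pytest.fixture
def scenario_dataset():
    """Mid-size dataset from the unequal-effects generative design."""
    cfg = SimConfig(n=600, h2=0.5, rho=0.1, beta=0.2, seed=99)
    data, truth = simulate_dataset(cfg)
    return data, truth, cfg
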