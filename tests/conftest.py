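import numpy as np
import pytest

from fcranker import FCRanker, generate, make_config, scenario


@pytest.fixture(scope="session")
def default_runs():
    """Fitted results on the default simulated scenario, seeds 1-5."""
    out = {}
    for seed in range(1, 6):
        coll = generate(scenario("default", seed=seed))
        res = FCRanker(coll, config=make_config(seed=seed)).fit()
        out[seed] = (coll, res)
    return out


@pytest.fixture(scope="session")
def null_runs():
    """Fitted results on the null (no-signal) scenario, seeds 1-5."""
    out = {}
    for seed in range(1, 6):
        coll = generate(scenario("null", seed=seed))
        res = FCRanker(coll, config=make_config(seed=seed, max_iterations=20)).fit()
        out[seed] = (coll, res)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
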