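import numpy as np
import pytest

from crossprime import SimConfig, make_test_community
from crossprime.synth import random_background


@pytest.fixture(scope="session")
def community(tmp_path_factory):
    """A small synthetic three-member community with truth tables."""
    out = tmp_path_factory.mktemp("community")
    config = SimConfig(seed=11, n_genes=3, gene_len=500, background_len=8000)
    paths = make_test_community(config, out)
    return config, paths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def background():
    """Deterministic 2-kb random template at 50% GC."""
    return random_background(2000, 50.0, np.random.default_rng(42))
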