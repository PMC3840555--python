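import numpy as np
import pytest

from divprof import Community


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_communities(rng, n_communities=20, max_taxa=50):
    """Random communities with positive abundances, varying richness."""
    out = []
    for i in range(n_communities):
        s = int(rng.integers(2, max_taxa + 1))
        abund = rng.gamma(0.5, size=s) + 1e-6
        out.append(Community([f"t{j}" for j in range(s)], abund, label=f"c{i}"))
    return out


@pytest.fixture
def communities(rng):
    return random_communities(rng)
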