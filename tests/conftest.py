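import numpy as np
import pytest

from knotarch.simulate import SimConfig, make_ancestor, apply_duplication


@pytest.fixture(scope="session")
def ancestor_gene():
    return make_ancestor(SimConfig(seed=42))


@pytest.fixture(scope="session")
def bivalent_gene(ancestor_gene):
    rng = np.random.default_rng(42)
    gene, _ = apply_duplication(ancestor_gene, rng)
    return gene


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
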