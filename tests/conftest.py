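import numpy as np
import pytest

from talemap.proteinmodel import DigestSpec
from talemap.synthetic import plant_links, synth_protein_pair


@pytest.fixture(scope="session")
def protein_pair():
    return synth_protein_pair(seed=7)


@pytest.fixture(scope="session")
def xlink_truth(protein_pair):
    return plant_links(protein_pair, n_true=10, n_decoys=10, seed=11)


@pytest.fixture(scope="session")
def digest_spec():
    return DigestSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
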