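import numpy as np
import pytest

from interpeprank import FixtureSpec, make_planted_dataset, make_toy_complex, make_toy_msa
from interpeprank.evolution_features import compute_profile


@pytest.fixture(scope="session")
def toy_native():
    """Small native complex: 55-residue helical receptor + 8-residue peptide."""
    return make_toy_complex(FixtureSpec(receptor_len=55, peptide_len=8, seed=11), "native")


@pytest.fixture(scope="session")
def toy_profile(toy_native):
    msa = make_toy_msa(toy_native.receptor_sequence(), depth=15, mutation_rate=0.3, seed=12)
    return compute_profile(msa)


@pytest.fixture(scope="session")
def mini_planted():
    """Shared small planted-signal dataset: 4 targets x 20 decoys."""
    return make_planted_dataset(4, 20, seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
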