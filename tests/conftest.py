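import numpy as np
import pytest

import codonbias as cb
from codonbias.cds_io import count_codons


@pytest.fixture(scope="session")
def default_cds_set():
    """One mid-sized synthetic species, shared across read-only tests."""
    records, truth = cb.generate_cds_set(cb.GeneratorConfig(seed=101, n_genes=250))
    return records, truth


@pytest.fixture(scope="session")
def default_profiles(default_cds_set):
    records, _ = default_cds_set
    tables = [count_codons(r) for r in records]
    return cb.profile_genes(tables), tables


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
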