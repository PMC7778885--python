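import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

import hicder as h

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def bt_small():
    """Two chromosomes, 100 kb bins: chrA has 4 bins, chrB 2 (last partial)."""
    return h.make_bintable([("chrA", 400_000), ("chrB", 150_000)], 100_000)


@pytest.fixture
def bt_chr6():
    """Single hg38-sized chr6 at the cancer-map resolution (40 kb)."""
    return h.make_bintable([("chr6", 170_805_979)], 40_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_matrix(bt, dense):
    """ContactMatrix from a dense symmetric array."""
    return h.ContactMatrix(bt, sp.coo_matrix(np.triu(dense)))


@pytest.fixture
def cm_small(bt_small, rng):
    from bruteforce_oracle import random_symmetric_counts

    return make_matrix(bt_small, random_symmetric_counts(rng, bt_small.n_bins))
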