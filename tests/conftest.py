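import numpy as np
import pytest

from eegrepair import MaskedMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_low_rank(rng, c, t, rank, scale=1.0):
    """Random incoherent low-rank matrix (Gaussian factors)."""
    return scale * (rng.normal(size=(c, rank)) @ rng.normal(size=(rank, t)))


def masked_low_rank(rng, c, t, rank, hidden_frac):
    """Low-rank matrix with a uniform random hidden set; every row and
    column is guaranteed at least one observed entry."""
    truth = random_low_rank(rng, c, t, rank)
    while True:
        mask = rng.random((c, t)) > hidden_frac
        blk = MaskedMatrix(truth, mask)
        if blk.is_completable():
            return blk, truth
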