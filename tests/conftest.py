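import numpy as np
import pytest

from polytrans.pore import PoreProfile
from polytrans.reference import benchmark_sequences
from polytrans.sequences import ChargeSequence, sample_sequences


@pytest.fixture(scope="session")
def bench():
    """Labelled benchmark sequences with their published statistics."""
    return benchmark_sequences()


@pytest.fixture(scope="session")
def flat_profile():
    """All site energies zero and no trans-bulk offset: symmetric random walk."""
    return PoreProfile(cation=(0.0,) * 7, anion=(0.0,) * 7, trans_bulk_offset=0.0)


@pytest.fixture(scope="session")
def random_sequences():
    """A small fixed set of random sequences of mixed lengths."""
    rng = np.random.default_rng(1234)
    seqs = []
    for k, n in enumerate([5, 7, 8, 12, 20, 20, 33]):
        charges = tuple(int(c) for c in rng.choice([-1, 1], size=n))
        seqs.append(ChargeSequence(charges, f"rnd{k}"))
    return seqs


@pytest.fixture(scope="session")
def q10_sample():
    return sample_sequences(20, 300, seed=99, Q=10)
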