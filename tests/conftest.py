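import numpy as np
import pytest

from p53re import ConsensusPattern, NucSequence


@pytest.fixture
def pattern():
    return ConsensusPattern()


@pytest.fixture
def rng():
    return np.random.default_rng(20200803)


def random_sequence(rng, length, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


@pytest.fixture
def random_seq_factory(rng):
    def make(length, identifier="rand"):
        return NucSequence(identifier, random_sequence(rng, length))

    return make
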