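import numpy as np
import pytest

from mitofinish import simulate
from mitofinish.records import SequenceRecord


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def kakapo_like_truth():
    """A 16 kbp genome carrying an 84 bp x 11 tandem repeat in the CR."""
    return simulate.simulate_mitogenome(
        base_len=16000,
        repeat_specs=[simulate.RepeatSpec(84, 11, position=500)],
        anchor_len=70,
        seed=3,
    )


@pytest.fixture(scope="session")
def plain_truth():
    """A 16 kbp genome with no repeats or duplications."""
    return simulate.simulate_mitogenome(base_len=16000, anchor_len=70, seed=11)


@pytest.fixture
def record_factory():
    def make(seq, id="seq", circular=False):
        return SequenceRecord(id, seq, circular=circular)

    return make
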