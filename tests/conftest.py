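import numpy as np
import pytest

from tandemdup.io import SequenceRecord
from tandemdup.simulate import decode, encode, mutate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutated(seq: str, p: float, rng: np.random.Generator) -> str:
    return decode(mutate(encode(seq), p, rng))


def substituted(seq: str, positions, rng: np.random.Generator) -> str:
    """Substitute exactly the given positions (each to a different base)."""
    codes = encode(seq).copy()
    for pos in positions:
        codes[pos] = (codes[pos] + rng.integers(1, 4)) % 4
    return decode(codes)


@pytest.fixture
def random_seq_factory(rng):
    return lambda length: random_seq(rng, length)
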