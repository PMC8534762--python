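import numpy as np
import pytest

from seqmif.sequence_io import ALPHABET, IUPAC_SETS


def random_sequence(rng: np.random.Generator, L: int, alphabet: str = ALPHABET) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), L))


def random_iupac_sequence(rng: np.random.Generator, L: int,
                          ambiguity_rate: float = 0.2) -> str:
    codes = sorted(IUPAC_SETS)
    out = []
    for _ in range(L):
        if rng.random() < ambiguity_rate:
            out.append(codes[rng.integers(len(codes))])
        else:
            out.append(ALPHABET[rng.integers(4)])
    return "".join(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
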