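import numpy as np
import pytest

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.35) -> str:
    at = (1 - gc) / 2
    return "".join(rng.choice(BASES, size=n, p=[at, gc / 2, gc / 2, at]))


@pytest.fixture
def rng():
    return np.random.default_rng(20120112)


@pytest.fixture
def make_dna():
    def _make(n: int, seed: int = 0, gc: float = 0.35) -> str:
        return random_dna(np.random.default_rng(seed), n, gc)

    return _make
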