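import numpy as np
import pytest

from scoremea.motifs import Background, MotifMatrix


@pytest.fixture(scope="session")
def uniform_bg() -> Background:
    return Background.uniform()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_motif(rng: np.random.Generator, width: int, max_count: int = 20) -> MotifMatrix:
    """A random count matrix with positive column sums."""
    counts = rng.integers(0, max_count, size=(4, width)).astype(float)
    zero_cols = counts.sum(axis=0) == 0
    counts[0, zero_cols] = 1.0
    return MotifMatrix(f"RND_{rng.integers(1 << 30)}", "random", counts)


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))
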