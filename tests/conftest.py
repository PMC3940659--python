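import numpy as np
import pytest

from idrscape.seq_io import ProteinRecord, STANDARD_AA

AA = np.array(list(STANDARD_AA))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA, size=length))


def random_protein(rng: np.random.Generator, length: int, pid: str = "P") -> ProteinRecord:
    return ProteinRecord(id=pid, sequence=random_sequence(rng, length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240301)


def random_intervals(rng: np.random.Generator, n: int, length: int):
    """Random (start, end) pairs within [1, length]."""
    out = []
    for _ in range(n):
        s = int(rng.integers(1, length + 1))
        e = int(rng.integers(s, length + 1))
        out.append((s, e))
    return out
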