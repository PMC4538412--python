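import numpy as np
import pytest

RNA = "ACGU"


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(RNA[b] for b in rng.integers(0, 4, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
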