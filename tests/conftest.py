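import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from promptfuse import BinaryMask


def random_binary(rng: np.random.Generator, h: int, w: int, p: float = 0.4) -> BinaryMask:
    return BinaryMask((rng.random((h, w)) < p).astype(np.uint8))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
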