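import numpy as np
import pytest

from motorlearn import LearnerParams


@pytest.fixture
def default_params() -> LearnerParams:
    return LearnerParams()


def seed_set(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)
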