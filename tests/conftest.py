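import numpy as np
import pytest

from gaintimer.histories import CNConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def timeable_states(max_cn: int = 7):
    """All timeable copy-number states up to the supported maximum."""
    return [
        CNConfig(nt, nb)
        for nt in range(2, max_cn + 1)
        for nb in range(0, nt // 2 + 1)
        if CNConfig(nt, nb).timeable
    ]
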