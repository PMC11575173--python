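import numpy as np
import pytest

from striephys.benchmarks import match_events  # noqa: F401 (fixture helper)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def match():
    """Greedy one-to-one event matcher: (detected, truth, tol) -> n_matched."""
    def _match(detected, truth, tol_s):
        n, _ = match_events(detected, truth, tol_s)
        return n
    return _match
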