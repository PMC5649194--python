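import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_flat_trace(n=50, lo=0.0, hi=200.0, force=0.0, ascending=True):
    sep = np.linspace(lo, hi, n)
    if not ascending:
        sep = sep[::-1]
    return np.column_stack([sep, np.full(n, force, dtype=float)])
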