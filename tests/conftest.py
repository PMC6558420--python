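import numpy as np
import pytest

from distoverlap import KernelSpec, Sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_spec():
    return KernelSpec()


@pytest.fixture
def normal_pair(rng):
    """Two well-sized Normal samples, N(0,1) and N(3,1)."""
    return (
        Sample("a", rng.normal(0.0, 1.0, 2000)),
        Sample("b", rng.normal(3.0, 1.0, 2000)),
    )
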