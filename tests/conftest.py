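import numpy as np
import pytest

from dscseg.nn import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def as_tensor(arr):
    return Tensor(np.asarray(arr, dtype=np.float32))


def set_identity_bn(bn):
    """Put a BatchNorm2d in unit-scale/zero-shift inference state."""
    bn.weight.data[...] = 1.0
    bn.bias.data[...] = 0.0
    bn._buffers["running_mean"][...] = 0.0
    bn._buffers["running_var"][...] = 1.0 - bn.eps  # so 1/sqrt(var+eps) == 1


@pytest.fixture
def tiny_scenes():
    from dscseg.data import generate_synthetic_field

    return generate_synthetic_field(4, 32, seed=9)
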