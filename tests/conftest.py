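import numpy as np
import pytest

from mpclogit import PrimeFieldBackend, RealBackend


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def real_backend():
    return RealBackend()


@pytest.fixture
def field_backend():
    return PrimeFieldBackend()


@pytest.fixture
def tiny_field():
    """Integer arithmetic mod 31 (no fixed point): exhaustive checks."""
    return PrimeFieldBackend(modulus=31, frac_bits=0)
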