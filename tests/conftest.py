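import numpy as np
import pytest

from eriwsta import DegradationSpec, degrade, shepp_logan_phantom, uniform_blur_operator


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def blur_instance():
    """Small seeded deblurring instance: (operator, measurement, truth image)."""
    truth = shepp_logan_phantom(32)
    spec = DegradationSpec(kernel_size=5, noise_variance=1e-2, seed=7, boundary="zero")
    op = uniform_blur_operator(truth.shape, spec)
    b = degrade(truth, op, spec)
    return op, b, truth
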