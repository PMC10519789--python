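import numpy as np
import pytest

from fcaeffnet.architecture import ArchitectureSpec, build_model
from fcaeffnet.synth import SynthSpec, generate_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_arch():
    """Smallest buildable member of the family: single-repeat deep stages,
    32 px input — used wherever a forward/backward pass is needed fast."""
    return ArchitectureSpec(layers_567=(1, 1, 2), input_resolution=32)


@pytest.fixture(scope="session")
def tiny_model(tiny_arch):
    return build_model(tiny_arch, seed=7)


@pytest.fixture(scope="session")
def synth_small():
    """A small rendered image set shared across tests (deterministic)."""
    spec = SynthSpec(n_per_class=8, resolution=48, background_clutter=0.25, seed=3)
    images, labels, classes = generate_arrays(spec)
    return spec, images, labels, classes
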