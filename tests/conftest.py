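import numpy as np
import pytest

from mrmotionsim import PhantomSpec, SimulationParams, generate_phantom, \
    normalize_volume


@pytest.fixture(scope="session")
def small_phantom():
    """Noisy 32x32x8 labelled phantom (session-scoped, read-only)."""
    spec = PhantomSpec(matrix_size=32, n_slices=8, noise_sd=0.01, seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noise_free_phantom():
    spec = PhantomSpec(matrix_size=32, n_slices=8, noise_sd=0.0, seed=7)
    return generate_phantom(spec)


@pytest.fixture
def default_params():
    return SimulationParams()
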