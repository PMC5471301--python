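import numpy as np
import pytest

from hemidti import synthetic as syn
from hemidti.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def small_scheme():
    """12-direction scheme: fast but well-posed for tensor fitting."""
    return syn.make_gradient_scheme(n_directions=12, b=800.0, n_b0=2)


@pytest.fixture(scope="session")
def default_scheme():
    return syn.make_gradient_scheme()


@pytest.fixture(scope="session")
def small_spec():
    return syn.PhantomSpec(grid_shape=(20, 20, 10), voxel_size=(2.0, 2.0, 2.8))


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return syn.build_phantom(small_spec)


@pytest.fixture(scope="session")
def tumor_spec():
    return syn.PhantomSpec(grid_shape=(24, 24, 12), voxel_size=(2.0, 2.0, 2.8),
                           tumor_center=(6.0, 12.0, 6.0), tumor_radius=6.0,
                           tumor_hemisphere="left")


@pytest.fixture(scope="session")
def tumor_phantom(tumor_spec):
    return syn.build_phantom(tumor_spec)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
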