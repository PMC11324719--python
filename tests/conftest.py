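import numpy as np
import pytest

from prostacoreg.phantom import PhantomSpec, generate_scene


@pytest.fixture(scope="session")
def small_spec():
    """Coarse, quick-to-voxelize phantom used across the suite."""
    return PhantomSpec(voxel_spacing=(1.0, 1.0, 1.0), seed=7)


@pytest.fixture(scope="session")
def scene(small_spec):
    return generate_scene(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
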