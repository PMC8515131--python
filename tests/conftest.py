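import numpy as np
import pytest

from bpequant.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def small_spec():
    """A quick 64^3 phantom spec used by several stages."""
    return PhantomSpec(grid_shape=(64, 64, 64), breast_radius=13.0,
                       chest_wall_depth=8.0, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(grid_shape=(64, 64, 64), breast_radius=13.0,
                       chest_wall_depth=8.0, noise_sigma=0.0, seed=7)
    return spec, make_phantom(spec)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
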