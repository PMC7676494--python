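import numpy as np
import pytest

from biopsy3d import phantom
from biopsy3d.volume_io import ChannelStack


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def textured_plane(rng):
    """A textured 96x96 plane with broad-band content for registration tests."""
    from scipy import ndimage

    base = ndimage.gaussian_filter(rng.standard_normal((96, 96)), 2.0)
    fine = rng.standard_normal((96, 96)) * 0.3
    plane = 100.0 + 20.0 * (base + fine)
    return np.clip(plane, 0, None)


@pytest.fixture(scope="session")
def small_phantom():
    """Desk-scale slab phantom with one 50 um and one 60 um spherical cavity."""
    spec = phantom.graded_cavity_spec(
        seed=0, diameters_um=(50.0, 60.0), volume_shape=(48, 160, 160)
    )
    return phantom.generate_phantom(spec)


@pytest.fixture(scope="session")
def small_bf(small_phantom):
    return phantom.simulate_bf_stack(small_phantom, seed=7)


def make_stack(volume, channel="BF", spacing=(3.0, 1.0, 1.0)):
    return ChannelStack.from_array(np.asarray(volume, dtype=np.float64), channel=channel, spacing_um=spacing)
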