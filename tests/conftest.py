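import numpy as np
import pytest

import kfmfit


@pytest.fixture(scope="session")
def small_phantom():
    """A small, fast phantom set shared by unit tests."""
    return kfmfit.generate_dataset(kfmfit.PhantomConfig(n_images=12, seed=3))


@pytest.fixture(scope="session")
def small_model(small_phantom):
    return kfmfit.train_model(
        [s.image for s in small_phantom], [s.shape for s in small_phantom]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ellipse_shape(n=38, a=60.0, b=40.0, center=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return kfmfit.LandmarkShape(
        np.c_[center[0] + a * np.cos(th), center[1] + b * np.sin(th)]
    )
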