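import numpy as np
import pytest

from vesselseg.config import tiny_config
from vesselseg.network import IBSwinUNet3D
from vesselseg.phantom import PhantomSpec, generate
from vesselseg.preprocessing import normalize
from vesselseg.training import train


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A 32³ two-generation phantom with known 3-branch topology."""
    spec = PhantomSpec(shape=(32, 32, 32), depth=2, root_radius_mm=2.5,
                       root_length_mm=12, seed=11)
    return generate(spec)


@pytest.fixture(scope="session")
def tiny_overfit(small_phantom):
    """Tiny-configuration network trained to overfit one phantom patch.

    Shared across training and end-to-end checks so the (CPU-minutes) run
    happens once per session.
    """
    cfg = tiny_config(seed=0)
    img = normalize(small_phantom.image)
    net = IBSwinUNet3D(base_channels=16, depths=(2,), window_size=(4, 4, 4), seed=0)
    state = train(net, [(img, small_phantom.label)], cfg, steps=300, log_every=0)
    return {"model": net, "image": img, "label": small_phantom.label,
            "state": state, "config": cfg}
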