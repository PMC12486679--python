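import numpy as np
import pytest

from monomech.fields import SubstrateSpec
from monomech.synthetic import NoiseModel, make_contractile_strip_scene


@pytest.fixture(scope="session")
def gel() -> SubstrateSpec:
    return SubstrateSpec(youngs_modulus=12000.0, poisson=0.457, thickness=50.0)


@pytest.fixture(scope="session")
def small_scene(gel):
    """Compact strip scene used by several stages (cheap to build once)."""
    return make_contractile_strip_scene(
        strip_width=240.0, peak_traction=100.0, profile="edge-localised",
        substrate=gel, seed=7, shape=(192, 256), pixel_size=2.0,
        edge_band_um=60.0, n_frames=2,
        noise=NoiseModel(bead_density=0.15, spot_sigma=0.8,
                         photon_noise_sd=0.02))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
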