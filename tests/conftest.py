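import numpy as np
import pytest

from aquaphase.registry import load_registry
from aquaphase.slab import density_profile
from aquaphase.synthetic import SlabSpec, gen_slab_frames


@pytest.fixture(scope="session")
def registry_models():
    return load_registry()


@pytest.fixture(scope="session")
def slab_frames():
    """200-frame synthetic slab at (1000, 10) g/L with fixed seed."""
    spec = SlabSpec(rho_l=1000.0, rho_v=10.0, n_frames=200, seed=1)
    frames, truth = gen_slab_frames(spec)
    return frames, truth


@pytest.fixture(scope="session")
def slab_profile_fixture(slab_frames):
    frames, truth = slab_frames
    return density_profile(frames, bin_width=0.5), truth


@pytest.fixture(scope="session")
def coexistence_grid():
    return np.arange(400.0, 621.0, 20.0)
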