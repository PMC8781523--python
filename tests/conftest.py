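import numpy as np
import pytest

from jmoct import SystemProfile, simulate_jones_volume, uniform_phantom


def small_system(**kwargs) -> SystemProfile:
    """Compact grid for fast unit tests."""
    defaults = dict(depth_pixels=64, x_pixels=16, y_pixels=16, n_repeats=1,
                    noise_floor_db=None)
    defaults.update(kwargs)
    return SystemProfile(**defaults)


@pytest.fixture
def uniform_jones():
    """Factory: simulate a uniform phantom with the given optical properties."""

    def make(mu=0.0, dn=0.0, *, seed=0, psf=False, **system_kwargs):
        spec = uniform_phantom(mu, dn, system=small_system(**system_kwargs),
                               seed=seed)
        return simulate_jones_volume(spec, psf=psf)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
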