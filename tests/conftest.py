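import numpy as np
import pytest

from gwjtv import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Compact noiseless phantom used by most junction-core tests."""
    return PhantomSpec(
        grid_shape=(48, 48, 48),
        csf_radius_mm=20.0,
        gm_radius_mm=16.0,
        wm_radius_mm=10.0,
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_seg(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def noisy_spec(small_spec):
    import dataclasses

    return dataclasses.replace(small_spec, noise_sd=2.0)


@pytest.fixture(scope="session")
def noisy_seg(noisy_spec):
    return make_phantom(noisy_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
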