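import pytest

from rssi_nwu import PhantomSpec, generate_phantom
from rssi_nwu.spatial import normalize_to_template


@pytest.fixture(scope="session")
def default_bundle():
    """Study-condition phantom: 1 HU noise, 2.6 HU thalamic texture, 10% NWU."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Deterministic phantom: no CT noise and no thalamic texture."""
    return generate_phantom(PhantomSpec(noise_sd_hu=0.0, thalamus_sd_hu=0.0, seed=2))


@pytest.fixture(scope="session")
def default_to_template(default_bundle):
    """Affine normalization of the default phantom CT onto the built-in template."""
    return normalize_to_template(default_bundle.ct)
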