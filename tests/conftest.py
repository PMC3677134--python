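import numpy as np
import pytest

from mpmrepro.phantom import (
    NULL_SITE_SPEC,
    SiteSpec,
    generate_phantom,
    generate_site,
)

# Test grid: 48^3 at 10/3 mm keeps the full 160 mm field of view of the
# default grid so the mm-scale anatomy (caudate blobs, callosal bridge) stays
# resolvable while every pipeline stage runs in seconds.
TEST_DIMS = (48, 48, 48)
TEST_VOX = 160.0 / 48.0


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(TEST_DIMS, TEST_VOX, seed=7)


@pytest.fixture(scope="session")
def null_site(phantom):
    """Site with unit fields, identity pose and zero noise."""
    return generate_site(phantom, NULL_SITE_SPEC, seed=11)


@pytest.fixture(scope="session")
def default_site(phantom):
    return generate_site(phantom, SiteSpec(), seed=12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
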