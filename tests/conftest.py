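import pytest
from hypothesis import HealthCheck, settings

import xovermap as xm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def site():
    return xm.default_site()


@pytest.fixture(scope="session")
def spec(site):
    return xm.LibrarySpec(site=site)


@pytest.fixture(scope="session")
def anchors(site):
    return xm.AnchorSet.from_site(site)
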