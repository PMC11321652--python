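import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import abescan as ab
from abescan import resources


@pytest.fixture(scope="session")
def tada8e() -> str:
    return resources.tada8e()


@pytest.fixture(scope="session")
def tada710() -> str:
    return resources.tada710()


@pytest.fixture(scope="session")
def hfe_fixture():
    return ab.make_locus_fixture("hfe_c282y")


@pytest.fixture(scope="session")
def hbb_fixture():
    return ab.make_locus_fixture("hbb_s")


@pytest.fixture(scope="session")
def reporter_fixture():
    return ab.make_locus_fixture("stop_egfp_reporter")


@pytest.fixture(scope="session")
def aavs1_spec():
    return ab.make_locus_fixture("aavs1_like").spec
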