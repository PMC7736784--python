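import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lib1():
    from compsel.presets import spytag_core_library
    return spytag_core_library()


@pytest.fixture(scope="session")
def lib2():
    from compsel.presets import spytag_flank_library
    return spytag_flank_library()


@pytest.fixture(scope="session")
def lib3():
    from compsel.presets import coevolution_library
    return coevolution_library()
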