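import pytest

from godiva_aos import (
    LesionConfig,
    build_control_timeline,
    default_calibration,
    load_fixture,
    simulate_aos,
)


@pytest.fixture(scope="session")
def cal():
    return default_calibration()


@pytest.fixture(scope="session")
def potato():
    return load_fixture("here_is_the_potato")


@pytest.fixture(scope="session")
def control_tl(potato, cal):
    return build_control_timeline(potato, cal)


@pytest.fixture(scope="session")
def aos_tl(potato, cal):
    return simulate_aos(potato, LesionConfig(), cal)
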