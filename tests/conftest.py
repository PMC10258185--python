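import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def evar_stim():
    """30 deg/s EVAR step, 120 s (long enough to fit an 18.7 s decay)."""
    from vsom.stimuli import make_paradigm

    return make_paradigm("EVAR", rate=30.0, duration=120.0)


@pytest.fixture(scope="session")
def svm_perception():
    from vsom.svm import SVMParams

    return SVMParams.preset("perception")


@pytest.fixture(scope="session")
def msom_perception():
    from vsom.msom import MSOMParams

    return MSOMParams.preset("perception")


@pytest.fixture(scope="session")
def pfm_perception():
    from vsom.pfm import PFMParams

    return PFMParams.preset("perception")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
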