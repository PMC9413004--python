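import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import taguchigra as tg

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return tg.build_l18()


@pytest.fixture(scope="session")
def study():
    return tg.load_study()


@pytest.fixture(scope="session")
def gra_result(study):
    return tg.gra_pipeline(study.responses)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
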