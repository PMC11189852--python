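import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from renaldwi import DT2Mesh, build_kernel, make_protocol

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def multi_b():
    return make_protocol("multi_b_12")


@pytest.fixture(scope="session")
def drcsi():
    return make_protocol("drcsi_6x6")


@pytest.fixture(scope="session")
def mesh():
    return DT2Mesh()


@pytest.fixture(scope="session")
def kernel(drcsi, mesh):
    return build_kernel(drcsi, mesh)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
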