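import pytest
from hypothesis import HealthCheck, settings

import receptorq as rq

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1():
    """Reference parameter set: Q=50 per 10 ms, trafficking time 4 s."""
    return rq.load_fixture("table1_q50_mu4")


@pytest.fixture(scope="session")
def table1_q100():
    """Same geometry and medium, Q=100 per 10 ms, trafficking time 4 s."""
    return rq.load_fixture("table1_q100_mu4")


@pytest.fixture(scope="session")
def table1_series(table1):
    return rq.build_rate_series(table1)
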