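import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from degradomics import classify, datasets

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_catalog():
    return datasets.table1_catalog()


@pytest.fixture(scope="session")
def table1_records():
    return datasets.table1_rq_records()


@pytest.fixture(scope="session")
def table1_calls(table1_records, table1_catalog):
    return classify(table1_records, table1_catalog, threshold=4.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
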