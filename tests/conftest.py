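import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rucuca():
    from flymap.core import rucuca_map

    return rucuca_map()


@pytest.fixture(scope="session")
def scored_males_table():
    from flymap.datasets import scored_males

    return scored_males()
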