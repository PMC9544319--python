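import numpy as np
import pytest

from robustmeta.datasets import (
    load_rituximab_rob,
    load_rituximab_studies,
    rituximab_all_domains_spec,
)


@pytest.fixture(scope="session")
def rituximab():
    return load_rituximab_studies()


@pytest.fixture(scope="session")
def rituximab_rob():
    return load_rituximab_rob()


@pytest.fixture(scope="session")
def all_domains_spec():
    return rituximab_all_domains_spec()


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)
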