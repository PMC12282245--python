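import pytest
from hypothesis import settings

import cefacall as cc
from cefacall.genotyper import get_catalog

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return cc.default_panel()


@pytest.fixture(scope="session")
def catalog(panel):
    return get_catalog(panel)


@pytest.fixture(scope="session")
def zero_params():
    return cc.zero_noise_params()
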