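import pytest
from hypothesis import settings

import cherryplex as cp

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return cp.load_default_panel()


@pytest.fixture(scope="session")
def zero_noise():
    """Deterministic generator settings: exact sizes and heights."""
    return cp.SimParams(cv=0.0, size_sd=0.0, seed=1)
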