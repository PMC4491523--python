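import numpy as np
import pytest

from pulsereduce.network import GlobalParams

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def globals_default() -> GlobalParams:
    return GlobalParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150417)
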