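"""Shared pytest fixtures."""

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
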