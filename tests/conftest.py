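import numpy as np
import pytest

from tectofit import make_variant_fixtures


@pytest.fixture(scope="session")
def variants():
    """Curated signature set keyed by construct id."""
    return {v.id: v for v in make_variant_fixtures()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20191)
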