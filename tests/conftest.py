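import numpy as np
import pytest

from bifidshunt.stoichiometry import SubstrateSpec


@pytest.fixture
def hexose2() -> SubstrateSpec:
    """A generic disaccharide of two plain hexoses (lactose-like)."""
    return SubstrateSpec("hexose2", 2, 0, 12, 342.30)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
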