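import numpy as np
import pytest

import spanner as sp


@pytest.fixture(scope="session")
def tax8() -> sp.Taxonomy:
    """Balanced 8-rank taxonomy: 2 domains, 16 genera, 32 species."""
    return sp.make_toy_taxonomy((2, 2, 1, 1, 2, 2, 2))


@pytest.fixture(scope="session")
def worked_example():
    """Two 3-match profiles plus a 4-rank taxonomy scoring exactly 1.375."""
    return sp.make_worked_example()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_915)
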