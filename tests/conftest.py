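import numpy as np
import pytest

from catscreen.synthdata import generate_library


@pytest.fixture(scope="session")
def random_molecules():
    """100 grammar-generated, washed molecules (fixed seed)."""
    mols, _ = generate_library(100, seed=11)
    return mols


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same stream regardless of
    # which other tests ran before it
    return np.random.default_rng(20260919)
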