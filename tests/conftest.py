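import numpy as np
import pytest

from hypersolv.molgraph import featurize_molecule


@pytest.fixture(scope="session")
def tiny_corpus():
    """Three small molecules sharing a C-C backbone."""
    return [featurize_molecule(s) for s in ("CCO", "CCN", "CCC")]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
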