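import numpy as np
import pytest

from tfannot.synthetic import gen_proteome


@pytest.fixture(scope="session")
def small_proteome():
    """A small labeled proteome shared across tests (fixed seed)."""
    return gen_proteome(n_tf_per_superclass=4, n_nontf=20, seed=7)


@pytest.fixture(scope="session")
def proteome_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("proteome")
    gen_proteome(n_tf_per_superclass=4, n_nontf=20, seed=7,
                 out_dir=str(out))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
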