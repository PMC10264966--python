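import numpy as np
import pytest

from thermomatch.synth import load_preset, noise_free


@pytest.fixture(scope="session")
def chlamy():
    return load_preset("chlamydomonas")


@pytest.fixture(scope="session")
def desmo():
    return load_preset("desmodesmus")


@pytest.fixture(scope="session")
def pair_chlamy():
    return load_preset("daphnia_on_chlamydomonas")


@pytest.fixture(scope="session")
def pair_desmo():
    return load_preset("daphnia_on_desmodesmus")


@pytest.fixture(scope="session")
def pair_chlamy_clean(pair_chlamy):
    return noise_free(pair_chlamy)


@pytest.fixture
def rng():
    return np.random.default_rng(20230613)
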