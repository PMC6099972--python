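import numpy as np
import pandas as pd
import pytest

from toxqsar import load_table1
from toxqsar.synthetic_data import SyntheticSpec, make_linear_dataset


@pytest.fixture(scope="session")
def groups():
    """All three groups of the packaged toxicity table."""
    return {g: load_table1(g) for g in (1, 2, 3)}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def linear_dataset():
    """Small planted-signal dataset: n=60, 3 true + 7 nuisance descriptors."""
    spec = SyntheticSpec(
        n=60, p_signal=3, p_noise=7, coefficients=(1.0, -2.0, 0.5), noise_sd=0.1, seed=7
    )
    return make_linear_dataset(spec)
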