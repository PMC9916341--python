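import numpy as np
import pytest

from aquarisk import synthetic


@pytest.fixture(scope="session")
def survey():
    """Default synthetic survey (35 mining / 20 non-mining / 5 mine-water)."""
    df, truth = synthetic.generate(seed=11)
    return df, truth


@pytest.fixture(scope="session")
def mixture3():
    """Three-source mixing data with receptor-model noise and known truth."""
    X, U, G, F = synthetic.generate_mixture(n=60, m=16, p=3, seed=2, noise=True)
    return X, U, G, F


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
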