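import numpy as np
import pytest

from pcm import LSHConfig, SyntheticSpec, from_dense, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_matrix(rng):
    """A dense 8x5 nonnegative matrix with two identical patient rows."""
    values = rng.uniform(0.0, 10.0, size=(8, 5))
    values[7] = values[0]  # p8 duplicates p1
    return from_dense(values)


@pytest.fixture
def sparse_matrix(rng):
    """A 20x6 matrix with ~25% missing entries, every row/col observed."""
    values = rng.uniform(0.0, 5.0, size=(20, 6))
    mask = rng.random((20, 6)) < 0.25
    for i in range(20):  # keep at least two observations per patient
        mask[i, rng.choice(6, size=2, replace=False)] = False
    mask[:, mask.all(axis=0)] = False
    values[mask] = np.nan
    return from_dense(values)


def planted_fixture(seed: int, m: int = 200, n: int = 120, noise_sd: float = 0.5):
    """The reduced-scale planted-cluster fixture used throughout the suite:
    4 equal groups with disjoint signature-disease blocks."""
    spec = SyntheticSpec(m=m, n=n, g=4, noise_sd=noise_sd, seed=seed)
    return generate(spec)


@pytest.fixture
def default_config():
    return LSHConfig(c=2, r=4, k=8, seed=11)
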