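import numpy as np
import pytest

from mslesions import dwi, synthetic


@pytest.fixture(scope="session")
def scheme():
    """Three-shell acquisition: 60 directions each at b=1000/2000/3000 + 5 b=0."""
    return dwi.default_scheme()


@pytest.fixture(scope="session")
def small_cohort():
    """Default 59-patient synthetic cohort, seed 11."""
    cfg = synthetic.CohortConfig(seed=11)
    return synthetic.gen_cohort(cfg)


@pytest.fixture(scope="session")
def typing_features():
    """1000 lesions on the four typing metrics with latent truth."""
    return synthetic.gen_typing_benchmark(n_lesions=1000, seed=21)


@pytest.fixture(scope="session")
def phantom():
    return synthetic.gen_phantom_masks(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
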