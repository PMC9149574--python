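import numpy as np
import pytest

from mmlassonet import CohortConfig, PathConfig, SplitSpec, generate_cohort, split_dataset

# desk-scale cohort for generic pipeline tests (smaller than the default
# study config so the whole suite stays fast)
SMALL_CONFIG = dict(n_per_group=12, T=24, R=12, informative_rois=(0, 1, 2), seed=7)

# fast training settings for tests that only need qualitative behaviour
FAST_PATH = dict(epochs_per_lambda=20, epsilon=0.05, hidden_K=16)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_splits(small_cohort):
    return split_dataset(small_cohort, SplitSpec(seed=1))


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-scale cohort (n=60, T=60, R=30, 5 informative ROIs)."""
    return generate_cohort(CohortConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
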