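import numpy as np
import pytest

from qfoa import FitnessConfig, SyntheticSpec, generate_feature_dataset
from qfoa.tuning import prior_knowledge_zoom


@pytest.fixture(scope="session")
def default_cohort():
    """Train/test cohort with the default sizes (58 train / 56 test) and separation 6."""
    return generate_feature_dataset(SyntheticSpec())


@pytest.fixture(scope="session")
def synthetic_zoom(default_cohort):
    """Prior-knowledge zoom multiples scanned once on the default training set."""
    train, _ = default_cohort
    return prior_knowledge_zoom(train, FitnessConfig(), fold_seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
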