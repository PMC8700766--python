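import numpy as np
import pytest

from tpecascade import CascadeConfig, Family, builtin_profiles, make_dataset

#: tiny tree counts so structural tests run in seconds; structural laws do
#: not depend on ensemble size
TINY_TREES = {family: {"n_estimators": 5} for family in Family}
SMALL_TREES = {family: {"n_estimators": 15} for family in Family}


@pytest.fixture(scope="session")
def separable_toy():
    """20 x 4 linearly separable toy: feature 0 determines the label."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((20, 4))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += np.where(y == 1, 3.0, -3.0)
    return X, y


@pytest.fixture(scope="session")
def learnable_data():
    """A mid-size learnable binary dataset (breast-mass-shaped, strong signal)."""
    profile = builtin_profiles()["breast-like"].replace(signal_strength=3.0)
    X, y, meta = make_dataset(profile, seed=7)
    return X.to_numpy(dtype=float), y, meta


@pytest.fixture(scope="session")
def tiny_cascade_config():
    return CascadeConfig(max_depth=2, patience=1, k_inner=2, seed=11,
                         learner_params=TINY_TREES)
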