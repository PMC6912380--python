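import numpy as np
import pytest

from mc4pred import SyntheticConfig, generate_synthetic, train_4mcpred_el

#: Tiny grids for unit tests of the training machinery (not the defaults).
TINY_GRIDS = {
    "RF": {"n_estimators": [40]},
    "ERT": {"n_estimators": [40]},
    "GB": {"n_estimators": [30], "max_depth": [2], "max_features": ["sqrt"]},
    "SVM": {"C": [1.0]},
}


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def tiny_training_set():
    """Small planted-signal dataset for exercising the training machinery."""
    return generate_synthetic(SyntheticConfig(n_per_class=40, effect_size=0.8, seed=5))


@pytest.fixture(scope="session")
def tiny_model(tiny_training_set):
    """A fully trained (28 base + 4 meta) ensemble on the tiny dataset."""
    return train_4mcpred_el(
        tiny_training_set, seed=7, grids=TINY_GRIDS, cv_folds=3, oof_folds=3
    )
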