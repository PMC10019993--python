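import numpy as np
import pandas as pd
import pytest

from roachloop.arena_metrics import generate_grid
from roachloop.imu_features import FEATURE_COLUMNS
from roachloop.motion_classification import default_specs, train_classifier
from roachloop.synthetic_data import make_labeled_dataset


@pytest.fixture(scope="session")
def grid100():
    return generate_grid(100)


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced 60-per-class training table from the two training animals."""
    return make_labeled_dataset(60, seed=7)


@pytest.fixture(scope="session")
def linear_svm_model(small_dataset):
    return train_classifier(small_dataset, default_specs()["svm_linear"])


def synthetic_feature_table(n_per_class: int, separation: float,
                            seed: int = 0) -> pd.DataFrame:
    """Gaussian feature table with a controllable class-mean separation."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(0.0, 1.0, (n, len(FEATURE_COLUMNS)))
    y = np.repeat([0, 1], n_per_class)
    X[y == 1] += separation
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    df["label"] = y
    df["animal_id"] = "synthetic"
    return df
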