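import numpy as np
import pytest

from gradepanel.feature_selection import SelectionConfig
from gradepanel.hierarchy import HierarchyBuildConfig
from gradepanel.resampling import ResamplingConfig
from gradepanel.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_sim_config():
    """Compact simulation: three imbalanced classes, strong markers.

    Effect size is raised and dropout removed so structural and behavioural
    tests are not confounded by borderline separability.
    """
    return SimulationConfig(
        class_sizes=[10, 24, 14],
        n_features=200,
        markers_per_class=3,
        effect_size=5.0,
        dropout_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_sim_config):
    return simulate(small_sim_config)


@pytest.fixture(scope="session")
def fast_build_config():
    """Hierarchy config scaled for unit-test speed."""
    return HierarchyBuildConfig(
        cv_folds=3,
        resampling=ResamplingConfig(seed=0),
        selection=SelectionConfig(
            top_k=25, max_features=5, max_trials_per_step=5,
            inner_cv_folds=3, inner_cv_repeats=1,
        ),
        min_class_size=2,
        seed=0,
    )


@pytest.fixture(scope="session")
def trained_small(small_dataset, fast_build_config):
    from gradepanel.hierarchy import train_model

    return train_model(small_dataset.matrix, small_dataset.labels, fast_build_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
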