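import numpy as np
import pytest

from synspan import (TrainConfig, arcsinh_transform, balanced_downsample,
                     default_cortex_scenario, generate_events)


@pytest.fixture(scope="session")
def small_scenario():
    """Scaled-down cortex scenario: 500 events/subject, 7,500 events total."""
    return default_cortex_scenario(events_per_subject=500)


@pytest.fixture(scope="session")
def small_table(small_scenario):
    return generate_events(small_scenario, seed=1)


@pytest.fixture(scope="session")
def small_balanced(small_table):
    transformed = arcsinh_transform(small_table)
    return balanced_downsample(transformed, per_species=2000, seed=0)


@pytest.fixture
def fast_train_config():
    """Small network / short schedule for unit tests."""
    return TrainConfig(latent_dim=4, hidden_layers=(16, 8), batch_size=256,
                       max_epochs_pretrain=30, max_epochs_finetune=15, n_runs=2)


@pytest.fixture
def blobs_3():
    """Three well-separated 10-d Gaussian blobs with labels."""
    rng = np.random.default_rng(42)
    centers = np.array([[0.0] * 10, [8.0] * 10, [-8.0] * 10])
    X = np.vstack([rng.normal(c, 0.5, size=(400, 10)) for c in centers])
    y = np.repeat([0, 1, 2], 400)
    return X, y
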