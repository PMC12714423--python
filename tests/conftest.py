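import numpy as np
import pytest

from collarbehavior.classify import segments_to_xy, train_balanced_forest
from collarbehavior.label import segments_to_frame
from collarbehavior.simulate import SimConfig, simulate_dataset, training_segments


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(n_animals=6, duration_hours=6.0, seed=11)


@pytest.fixture(scope="session")
def sim_animals(sim_config):
    return simulate_dataset(sim_config)


@pytest.fixture(scope="session")
def segments(sim_animals):
    return training_segments(sim_animals, min_purity=1.0)


@pytest.fixture(scope="session")
def segments_frame(segments):
    return segments_to_frame(segments)


@pytest.fixture(scope="session")
def trained_model(segments):
    X, y = segments_to_xy(segments)
    return train_balanced_forest(X, y, n_trees=201, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
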