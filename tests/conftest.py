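import numpy as np
import pytest

import fallkit as fk
from fallkit.classifier import ClassifierConfig, train


@pytest.fixture(scope="session")
def small_config():
    """A reduced synthetic corpus for unit tests: 5 subjects, 8 traces each."""
    return fk.SyntheticConfig(seed=11, n_subjects=5, falls_per_subject=4, adls_per_subject=4)


@pytest.fixture(scope="session")
def small_traces(small_config):
    traces, _ = fk.generate_dataset(small_config)
    return traces


@pytest.fixture(scope="session")
def small_patterns(small_traces):
    return fk.patterns_from_traces(small_traces)


@pytest.fixture(scope="session")
def small_split(small_patterns):
    return fk.partition_by_subject(small_patterns, split=3, expected_subjects=5)


@pytest.fixture(scope="session")
def quick_model(small_split):
    """A briefly trained model: enough epochs to separate the synthetic classes."""
    train_p, val_p, _ = small_split
    return train(train_p, val_p, ClassifierConfig(seed=7, epochs=25))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
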