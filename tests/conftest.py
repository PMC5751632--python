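import numpy as np
import pytest

from eatbn import (
    build_default_structure,
    generate_dataset,
    segment_windows,
    train_model,
)


@pytest.fixture(scope="session")
def default_structure():
    return build_default_structure()


@pytest.fixture(scope="session")
def synthetic_dataset():
    """A seeded medium-size synthetic recording: records, annotations, windows."""
    records, annotations = generate_dataset(
        n_subjects=4, minutes_per_subject=6.0, seed=20770
    )
    windows = segment_windows(records)
    return records, annotations, windows


@pytest.fixture(scope="session")
def trained_model(default_structure, synthetic_dataset):
    _, annotations, windows = synthetic_dataset
    return train_model(windows, annotations, default_structure)


@pytest.fixture(scope="session")
def train_test_windows(synthetic_dataset):
    """Deterministic interleaved train/test split of the synthetic windows."""
    _, annotations, windows = synthetic_dataset
    rng = np.random.default_rng(99)
    order = rng.permutation(len(windows))
    train = [windows[i] for i in order[::2]]
    test = [windows[i] for i in order[1::2]]
    return train, test, annotations
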