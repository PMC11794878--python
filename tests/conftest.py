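import numpy as np
import pytest

from acrfs import Dataset, RunConfig, SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_spec():
    """A reduced synthetic spec for fast unit tests."""
    return SyntheticSpec(
        n_majority=120,
        n_minority=80,
        n_primary=6,
        n_secondary=3,
        n_noise=3,
        seed=11,
    )


@pytest.fixture
def small_dataset(small_spec):
    dataset, _ = generate_dataset(small_spec)
    return dataset


@pytest.fixture
def small_truth(small_spec):
    _, truth = generate_dataset(small_spec)
    return truth


@pytest.fixture
def default_config():
    return RunConfig()


@pytest.fixture
def tiny_dataset():
    """Four samples, three hand-written features, balanced labels."""
    return Dataset(
        features=np.array(
            [
                [1.0, 5.0, 0.0],
                [2.0, 4.0, 0.0],
                [3.0, 3.0, 1.0],
                [4.0, 2.0, 1.0],
            ]
        ),
        labels=np.array([0, 0, 1, 1]),
        feature_names=["up", "down", "binary"],
        label_name="y",
    )
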