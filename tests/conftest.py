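import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")

from eegsampling import ClassDataset, RunConfig, SignalRecord, generate_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_dataset():
    """3 channels x 32 samples, deterministic content."""
    gen = np.random.default_rng(7)
    records = [
        SignalRecord(
            channel_id=f"ch{i}", class_label="A", samples=gen.normal(size=32)
        )
        for i in range(3)
    ]
    return ClassDataset(class_label="A", records=records)


@pytest.fixture(scope="session")
def small_corpus():
    """5 well-separated classes x 12 channels x 512 samples."""
    return generate_benchmark(5, 12, 512, seed=11, separation=6.0)


@pytest.fixture
def fast_config():
    return RunConfig(
        scheme="RS",
        classifier="knn",
        knn_k=1,
        n_folds=4,
        n_repetitions=1,
        seed=5,
    )
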